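import os

import h5py
import numpy as np
import pytest

from managedh5 import (
    DatasetSpec,
    GroupSpec,
    ManagedTypeRegistry,
    add_entry,
    create_external_managed_object,
    create_managed_file,
    create_managed_object,
    create_multifile_container,
    find_managed_objects,
    generate_ephys_session,
    inject_violation,
    verify_compliance,
    wrap_managed_object,
)
from managedh5.errors import CreationError, RegistryError, SpecValidationError
from managedh5.managed import MANAGED_TYPE_ATTR
from managedh5.registry import DEFAULT_REGISTRY

from _helpers import walk_managed_paths


class TestRegistry:
    def test_duplicate_name_errors(self):
        reg = ManagedTypeRegistry()
        reg.register("T", lambda: GroupSpec(group="t"))
        with pytest.raises(RegistryError):
            reg.register("T", lambda: GroupSpec(group="t"))

    def test_invalid_spec_factory_carries_report(self):
        reg = ManagedTypeRegistry()
        with pytest.raises(SpecValidationError) as exc:
            reg.register("Bad", lambda: GroupSpec(group=None, prefix=None))
        assert exc.value.report

    def test_unregistered_base_errors(self):
        reg = ManagedTypeRegistry()
        with pytest.raises(RegistryError):
            reg.register("T", lambda: GroupSpec(group="t"), base="Nope")

    def test_derived_spec_contains_base_required_objects(self):
        base = DEFAULT_REGISTRY.spec("BrainDataEphys")
        derived = DEFAULT_REGISTRY.spec("BrainDataEphysProcessed")
        required = {
            k for k, v in base.datasets.items() if not v.optional
        }
        assert required <= set(derived.datasets)
        # and the derived type adds the band scale on top
        assert "band" in derived.datasets

    def test_subtype_chain(self):
        assert DEFAULT_REGISTRY.is_subtype(
            "BrainDataEphysProcessed", "BrainDataEphys"
        )
        assert not DEFAULT_REGISTRY.is_subtype(
            "BrainDataEphys", "BrainDataEphysProcessed"
        )


def _make_ephys(parent, name="ephys_data_dev", n=4, t=100, rate=12200.0):
    return create_managed_object(
        parent,
        "BrainDataEphys",
        name=name,
        payload=dict(
            raw=np.zeros((n, t)),
            sampling_rate=rate,
            electrode_ids=np.arange(n),
        ),
    )


class TestCreateAndWrap:
    def test_create_ephys_is_compliant(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            handle = _make_ephys(f)
            assert handle.managed_type == "BrainDataEphys"
            assert verify_compliance(handle).compliant

    def test_sibling_collision_leaves_file_unchanged(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            _make_ephys(f)
            before = sorted(f.keys())
            with pytest.raises(CreationError):
                _make_ephys(f)
            assert sorted(f.keys()) == before

    def test_failed_populate_rolls_back(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            with pytest.raises(CreationError):
                create_managed_object(
                    f,
                    "BrainDataEphys",
                    name="ephys_data_bad",
                    payload=dict(
                        raw=np.zeros((4, 10)),
                        sampling_rate=-1.0,  # invalid
                        electrode_ids=np.arange(4),
                    ),
                )
            assert "ephys_data_bad" not in f

    def test_create_then_wrap_has_identical_descriptors(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            created = _make_ephys(f)
            wrapped = wrap_managed_object(f, created.path)
            assert wrapped.managed_type == created.managed_type
            assert wrapped.description == created.description
            assert wrapped.stored_spec == created.stored_spec

    def test_wrap_dispatches_typed_handle(self, tmp_path):
        from managedh5 import EphysGroup

        with h5py.File(tmp_path / "f.h5", "w") as f:
            h = _make_ephys(f)
            assert isinstance(wrap_managed_object(f, h.path), EphysGroup)

    def test_wrap_plain_group_is_unmanaged(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            f.create_group("plain")
            h = wrap_managed_object(f, "/plain")
            assert h.unmanaged

    def test_wrap_unregistered_type_warns(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            g = f.create_group("odd")
            g.attrs[MANAGED_TYPE_ATTR] = "NotAType"
            with pytest.warns(UserWarning, match="NotAType"):
                h = wrap_managed_object(f, "/odd")
            assert h.warnings


class TestVerification:
    def test_extra_objects_keep_compliance(self, tmp_path):
        with h5py.File(tmp_path / "f.h5", "w") as f:
            handle = _make_ephys(f)
            handle.obj.create_dataset("my_extra", data=[1, 2, 3])
            handle.obj.create_group("my_notes").attrs["who"] = "me"
            assert verify_compliance(handle).compliant

    def test_deleted_required_dataset_is_found_at_path(self, session_path):
        violation = inject_violation(session_path, "delete_required")
        with h5py.File(session_path, "r") as h5:
            report = verify_compliance(h5)
        assert not report.compliant
        assert any(
            f.path == violation.path and f.rule == violation.rule
            for f in report.errors()
        )

    def test_wrong_fixed_attribute_value(self, session_path):
        violation = inject_violation(session_path, "wrong_attribute_value")
        with h5py.File(session_path, "r") as h5:
            report = verify_compliance(h5)
        assert any(
            f.path == violation.path and f.rule == "fixed-attribute-value"
            for f in report.errors()
        )

    def test_scale_length_mismatch(self, session_path):
        violation = inject_violation(session_path, "scale_length_mismatch")
        with h5py.File(session_path, "r") as h5:
            report = verify_compliance(h5)
        assert any(
            f.path == violation.path and f.rule == "dimension-scale-length"
            for f in report.errors()
        )

    def test_unverifiable_object_raises_distinct_error(self, tmp_path):
        from managedh5.errors import VerificationError

        with h5py.File(tmp_path / "f.h5", "w") as f:
            f.create_group("plain")
            with pytest.raises(VerificationError):
                verify_compliance(f["plain"])


class TestFind:
    def test_find_matches_exhaustive_walk(self, session_path):
        with h5py.File(session_path, "r") as h5:
            oracle = walk_managed_paths(h5)
            got = [(h.path, h.managed_type) for h in find_managed_objects(h5)]
            assert got == sorted(oracle)

    def test_type_filter_includes_subtypes(self, session_path):
        with h5py.File(session_path, "r") as h5:
            all_ephys = find_managed_objects(h5, "BrainDataEphys")
            types = {h.managed_type for h in all_ephys}
            assert types == {"BrainDataEphys", "BrainDataEphysProcessed"}
            exact = find_managed_objects(h5, "BrainDataEphys", exact=True)
            assert {h.managed_type for h in exact} == {"BrainDataEphys"}

    def test_empty_file_yields_nothing(self, tmp_path):
        with h5py.File(tmp_path / "e.h5", "w") as f:
            assert find_managed_objects(f) == []

    def test_non_recursive_sees_only_top_level(self, session_path):
        with h5py.File(session_path, "r") as h5:
            top = find_managed_objects(h5["/data/internal"], recursive=False)
            assert all(h.managed_type == "BrainDataCollection" for h in top)
            assert len(top) == 2


class TestExternalStorage:
    def test_external_object_found_like_internal(self, tmp_path):
        with h5py.File(tmp_path / "main.h5", "w") as f:
            create_external_managed_object(
                f["/"],
                "BrainDataEphys",
                external_path=str(tmp_path / "ext.h5"),
                name="ephys_data_ext",
                payload=dict(
                    raw=np.zeros((3, 20)),
                    sampling_rate=100.0,
                    electrode_ids=np.arange(3),
                ),
            )
            found = find_managed_objects(f)
            assert [h.path for h in found] == ["/ephys_data_ext"]
            assert found[0].managed_type == "BrainDataEphys"

    def test_external_file_is_verifiable_container(self, tmp_path):
        with h5py.File(tmp_path / "main.h5", "w") as f:
            create_external_managed_object(
                f["/"],
                "BrainDataEphys",
                external_path=str(tmp_path / "ext.h5"),
                name="ephys_data_ext",
                payload=dict(
                    raw=np.zeros((3, 20)),
                    sampling_rate=100.0,
                    electrode_ids=np.arange(3),
                ),
            )
        with h5py.File(tmp_path / "ext.h5", "r") as ext:
            root = wrap_managed_object(ext, "/")
            assert root.managed_type == "ManagedObjectContainer"
            assert verify_compliance(ext).compliant

    def test_deleted_external_file_reports_broken_link(self, tmp_path):
        path = tmp_path / "main.h5"
        with h5py.File(path, "w") as f:
            handle = _make_ephys(f, name="ephys_data_holder", n=2, t=5)
            create_external_managed_object(
                handle.obj,
                "BrainDataEphys",
                external_path=str(tmp_path / "gone.h5"),
                name="ephys_data_gone",
                payload=dict(
                    raw=np.zeros((2, 5)),
                    sampling_rate=100.0,
                    electrode_ids=np.arange(2),
                ),
            )
        os.unlink(tmp_path / "gone.h5")
        with h5py.File(path, "r") as f:
            report = verify_compliance(f["/ephys_data_holder"])
        assert any(f_.rule == "broken-link" for f_ in report.errors())

    def test_internal_and_external_reports_identical(self, tmp_path):
        payload = dict(
            raw=np.linspace(0, 1, 60).reshape(3, 20),
            sampling_rate=100.0,
            electrode_ids=np.arange(3),
        )
        with h5py.File(tmp_path / "a.h5", "w") as f:
            internal = create_managed_object(
                f, "BrainDataEphys", name="ephys_data_x", payload=dict(payload)
            )
            rep_int = verify_compliance(internal)
        with h5py.File(tmp_path / "b.h5", "w") as f:
            external = create_external_managed_object(
                f["/"],
                "BrainDataEphys",
                external_path=str(tmp_path / "b_ext.h5"),
                name="ephys_data_x",
                payload=dict(payload),
            )
            rep_ext = verify_compliance(external)
        assert rep_int.compliant and rep_ext.compliant
        assert [f_.to_obj() for f_ in rep_int.findings] == [
            f_.to_obj() for f_ in rep_ext.findings
        ]


class TestMultiFile:
    def _member(self, path):
        h = create_managed_file(str(path), "BrainDataFile")
        h.close()
        return str(path)

    def test_entries_dense_and_ordered(self, tmp_path):
        members = [self._member(tmp_path / f"m{i}.h5") for i in range(3)]
        container = create_multifile_container(str(tmp_path / "c.h5"))
        names = [add_entry(container, m) for m in members]
        assert names == ["entry_0", "entry_1", "entry_2"]
        for i, m in enumerate(members):
            entry = container[f"entry_{i}"]
            assert entry.attrs[MANAGED_TYPE_ATTR] == "BrainDataFile"
        container.close()

    def test_empty_container_compliant(self, tmp_path):
        container = create_multifile_container(str(tmp_path / "c.h5"))
        assert verify_compliance(container).compliant
        container.close()

    def test_wrap_entry_resolves_member_root(self, tmp_path):
        m = self._member(tmp_path / "m.h5")
        container = create_multifile_container(str(tmp_path / "c.h5"))
        add_entry(container, m)
        handle = wrap_managed_object(container.obj.file, "/entry_0")
        assert handle.managed_type == "BrainDataFile"
        assert "data" in handle.obj
        container.close()

    def test_non_managed_member_rejected(self, tmp_path):
        with h5py.File(tmp_path / "plain.h5", "w") as f:
            f.create_dataset("x", data=[1])
        container = create_multifile_container(str(tmp_path / "c.h5"))
        with pytest.raises(CreationError):
            add_entry(container, str(tmp_path / "plain.h5"))
        container.close()

    def test_container_is_managed_multifile(self, tmp_path):
        container = create_multifile_container(str(tmp_path / "c.h5"))
        assert container.managed_type == "BrainDataMultiFile"
        container.close()
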