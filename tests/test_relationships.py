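import json

import h5py
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from managedh5 import (
    IMR_POSTFIXES,
    RELATIONSHIP_PREFIX,
    RelationshipDescriptor,
    RelationshipTarget,
    Selection,
    create_index_map_relationship,
    create_relationship_attribute,
    find_relationships,
    get_index_map_relationships,
    imr_map,
    list_relationship_attributes,
    map_selection,
    select_through,
)
from managedh5.errors import (
    NoImpliedMappingError,
    ObjectLookupError,
    RelationshipError,
    SelectionBoundsError,
)

from _helpers import (
    check_mapping_against_oracle,
    make_relationship,
    memfile,
    oracle_imr_pairs,
    random_selection,
    selection_indices,
)


def _simple_rel(f, rtype, src_data, tgt_data, name="r", **kwargs):
    a = f.create_dataset("a", data=src_data)
    b = f.create_dataset("b", data=tgt_data)
    rel = create_relationship_attribute(
        a,
        name,
        RelationshipDescriptor(
            relationship_type=rtype,
            source_axes=[0],
            target=RelationshipTarget(location="/b", axes=[0]),
            **kwargs,
        ),
    )
    return rel, a, b


class TestCreateAndDiscover:
    def test_round_trips_through_close_and_reopen(self, tmp_path):
        path = tmp_path / "f.h5"
        with h5py.File(path, "w") as f:
            rel, _, _ = _simple_rel(f, "order", np.arange(5), np.arange(5))
            stored = rel.descriptor.to_dict()
        with h5py.File(path, "r") as f:
            rels = list_relationship_attributes(f["a"])
            assert len(rels) == 1
            assert rels[0].descriptor.to_dict() == stored

    def test_attribute_name_carries_reserved_prefix(self):
        with memfile() as f:
            rel, a, _ = _simple_rel(f, "order", np.arange(3), np.arange(3))
            assert rel.attr_name == RELATIONSHIP_PREFIX + "r"
            assert rel.attr_name in a.attrs
            json.loads(a.attrs[rel.attr_name])  # value is a JSON document

    def test_duplicate_name_collides(self):
        with memfile() as f:
            _simple_rel(f, "order", np.arange(3), np.arange(3))
            with pytest.raises(RelationshipError):
                create_relationship_attribute(
                    f["a"],
                    "r",
                    RelationshipDescriptor(
                        relationship_type="order",
                        target=RelationshipTarget(location="/b"),
                    ),
                )

    def test_unknown_type_rejected(self):
        with memfile() as f:
            f.create_dataset("a", data=[1])
            with pytest.raises(RelationshipError):
                create_relationship_attribute(
                    f["a"],
                    "r",
                    RelationshipDescriptor(
                        relationship_type="nope",
                        target=RelationshipTarget(location="/a"),
                    ),
                )

    def test_dangling_target_needs_explicit_flag(self):
        with memfile() as f:
            f.create_dataset("a", data=[1])
            desc = RelationshipDescriptor(
                relationship_type="order",
                target=RelationshipTarget(location="/missing"),
            )
            with pytest.raises(ObjectLookupError):
                create_relationship_attribute(f["a"], "r", desc)
            with pytest.warns(UserWarning, match="dangling"):
                create_relationship_attribute(
                    f["a"], "r", desc, allow_dangling=True
                )

    def test_list_filters_plain_attributes(self):
        with memfile() as f:
            a = f.create_dataset("a", data=[1])
            b = f.create_dataset("b", data=[1])
            a.attrs["plain1"] = 1
            a.attrs["plain2"] = "x"
            for i in range(3):
                create_relationship_attribute(
                    a,
                    f"rel{i}",
                    RelationshipDescriptor(
                        relationship_type="order",
                        target=RelationshipTarget(location="/b"),
                    ),
                )
            rels = list_relationship_attributes(a)
            assert [r.name for r in rels] == ["rel0", "rel1", "rel2"]

    def test_find_by_target(self, image_file):
        a = image_file["source_image"]
        b = image_file["target_image"]
        m = image_file["index_map"]
        assert [r.name for r in find_relationships(a, m)] == [
            "image_map" + IMR_POSTFIXES["SOURCE_TO_MAP"]
        ]
        assert find_relationships(a, b) == []  # no user leg in the fixture

    def test_find_user_leg_when_created(self, tmp_path, small_image_params):
        from dataclasses import replace

        from managedh5 import generate_image_scaling_fixture

        params = replace(small_image_params, include_user_leg=True)
        h5 = generate_image_scaling_fixture(params, str(tmp_path / "u.h5"))
        rels = find_relationships(h5["source_image"], h5["target_image"])
        assert [r.relationship_type for r in rels] == ["user"]
        h5.close()


class TestMappingExamples:
    def test_order_identity_range(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(f, "order", np.arange(10), np.arange(10))
            mapped = map_selection(rel, Selection.axes((slice(1, 4),)))
            assert mapped == Selection.axes((slice(1, 4),))

    def test_indexes_gather(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(
                f, "indexes", np.array([7, 3, 5]), np.arange(10)
            )
            mapped = map_selection(rel, Selection.axes(((0, 2),)))
            assert selection_indices(mapped, 10) == [7, 5]

    def test_shared_encoding_token_example(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(
                f,
                "shared_encoding",
                np.array([b"baa", b"gaa", b"baa"]),
                np.array([b"gaa", b"baa", b"baa"]),
            )
            mapped = map_selection(rel, Selection.axes((0,)))
            assert selection_indices(mapped, 3) == [1, 2]

    def test_shared_ascending_range_example(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(
                f,
                "shared_ascending_encoding",
                np.array([0, 10, 20, 30]),
                np.array([0, 5, 10, 15, 20, 25, 30]),
            )
            mapped = map_selection(rel, Selection.axes((slice(1, 3),)))
            assert mapped == Selection.axes((slice(2, 5),))

    def test_user_type_implies_no_mapping(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(f, "user", np.arange(3), np.arange(3))
            with pytest.raises(NoImpliedMappingError):
                map_selection(rel, Selection.axes((0,)))

    def test_zero_value_hits_is_empty_not_error(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(
                f, "shared_encoding", np.array([99]), np.array([1, 2, 3])
            )
            mapped = map_selection(rel, Selection.axes((0,)))
            assert mapped.is_empty()

    def test_out_of_bounds_selection(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(f, "order", np.arange(4), np.arange(4))
            with pytest.raises(SelectionBoundsError):
                map_selection(rel, Selection.axes((9,)))

    def test_equivalent_same_as_order(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(
                f, "equivalent", np.arange(6), np.arange(6) * 2
            )
            assert map_selection(rel, Selection.axes(((2, 4),))) == Selection.axes(
                ((2, 4),)
            )

    def test_group_order_uses_alphabetic_ordinals(self):
        with memfile() as f:
            ga = f.create_group("ga")
            gb = f.create_group("gb")
            for name in ("zeta", "alpha", "mid"):
                ga.create_dataset(name, data=[1])
            for name in ("c3", "a1", "b2"):
                gb.create_dataset(name, data=[1])
            rel = create_relationship_attribute(
                ga,
                "g",
                RelationshipDescriptor(
                    relationship_type="order",
                    target=RelationshipTarget(location="/gb"),
                ),
            )
            mapped = map_selection(rel, Selection.members(["alpha", "zeta"]))
            # alphabetic: alpha->0->a1, zeta->2->c3
            assert mapped == Selection.members(["a1", "c3"])


class TestSelectThrough:
    def test_indexes_compose(self):
        with memfile() as f:
            rel, _, b = _simple_rel(
                f, "indexes", np.array([7, 3, 5]), np.arange(10) * 10
            )
            vals = select_through(rel, Selection.axes(((0, 2),)))
            assert list(vals) == [70, 50]

    def test_order_equals_direct_read(self):
        with memfile() as f:
            tgt = np.arange(20) * 3.5
            rel, _, _ = _simple_rel(f, "order", np.arange(20), tgt)
            vals = select_through(rel, Selection.axes((slice(4, 9),)))
            assert np.array_equal(vals, tgt[4:9])

    def test_empty_mapped_selection_reads_empty(self):
        with memfile() as f:
            rel, _, _ = _simple_rel(
                f, "shared_encoding", np.array([99]), np.array([1, 2, 3])
            )
            vals = select_through(rel, Selection.axes((0,)))
            assert len(vals) == 0


class TestOracleEquivalence:
    """Dual-route check: implementation vs independent brute force."""

    MAPPING_TYPES = (
        "order",
        "equivalent",
        "indexes",
        "shared_encoding",
        "shared_ascending_encoding",
        "indexes_values",
    )

    @pytest.mark.parametrize("rtype", MAPPING_TYPES)
    def test_mapping_matches_brute_force(self, rtype):
        rng = np.random.default_rng(hash(rtype) % 2**32)
        with memfile() as f:
            for trial in range(60):
                rel, src_vals, tgt_vals = make_relationship(f, rng, rtype, trial)
                sel = random_selection(rng, len(src_vals))
                check_mapping_against_oracle(rel, sel, src_vals, tgt_vals)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_user_always_raises(self, seed):
        rng = np.random.default_rng(seed)
        with memfile() as f:
            rel, src_vals, _ = make_relationship(f, rng, "user", 0)
            with pytest.raises(NoImpliedMappingError):
                map_selection(rel, random_selection(rng, len(src_vals)))

    def test_ascending_equals_shared_when_values_unique(self):
        rng = np.random.default_rng(11)
        with memfile() as f:
            for trial in range(30):
                n = int(rng.integers(2, 30))
                src = np.sort(rng.choice(1000, size=n, replace=False))
                tgt = np.sort(rng.choice(1000, size=n, replace=False))
                a = f.create_dataset(f"sa{trial}", data=src)
                b = f.create_dataset(f"sb{trial}", data=tgt)
                kwargs = dict(
                    source_axes=[0],
                    target=RelationshipTarget(location=b.name, axes=[0]),
                )
                asc = create_relationship_attribute(
                    a, "asc", RelationshipDescriptor(
                        relationship_type="shared_ascending_encoding", **kwargs
                    ),
                )
                shr = create_relationship_attribute(
                    a, "shr", RelationshipDescriptor(
                        relationship_type="shared_encoding", **kwargs
                    ),
                )
                i = int(rng.integers(0, n))
                sel = Selection.axes((i,))  # point: both use value matching
                assert map_selection(asc, sel) == map_selection(shr, sel)

    def test_ascending_range_equals_shared_on_shared_value_pool(self):
        # when the (unique, sorted) target values are a subset of the source
        # values, range mapping by [min, max] and strict value matching agree
        rng = np.random.default_rng(13)
        with memfile() as f:
            for trial in range(30):
                n = int(rng.integers(3, 30))
                src = np.sort(rng.choice(1000, size=n, replace=False))
                m = int(rng.integers(1, n + 1))
                tgt = np.sort(rng.choice(src, size=m, replace=False))
                a = f.create_dataset(f"pa{trial}", data=src)
                b = f.create_dataset(f"pb{trial}", data=tgt)
                kwargs = dict(
                    source_axes=[0],
                    target=RelationshipTarget(location=b.name, axes=[0]),
                )
                asc = create_relationship_attribute(
                    a, "asc", RelationshipDescriptor(
                        relationship_type="shared_ascending_encoding", **kwargs
                    ),
                )
                shr = create_relationship_attribute(
                    a, "shr", RelationshipDescriptor(
                        relationship_type="shared_encoding", **kwargs
                    ),
                )
                lo = int(rng.integers(0, n))
                hi = int(rng.integers(lo, n + 1))
                sel = Selection.axes((slice(lo, hi),))
                from _helpers import selection_indices as _si

                assert _si(map_selection(asc, sel), m) == _si(
                    map_selection(shr, sel), m
                )

    def test_ascending_range_on_sorted_target_is_contiguous(self):
        rng = np.random.default_rng(12)
        with memfile() as f:
            for trial in range(30):
                n = int(rng.integers(2, 40))
                src = np.sort(rng.integers(0, 50, size=n))
                tgt = np.sort(rng.integers(0, 50, size=int(rng.integers(1, 40))))
                a = f.create_dataset(f"ra{trial}", data=src)
                b = f.create_dataset(f"rb{trial}", data=tgt)
                rel = create_relationship_attribute(
                    a,
                    "rng",
                    RelationshipDescriptor(
                        relationship_type="shared_ascending_encoding",
                        source_axes=[0],
                        target=RelationshipTarget(location=b.name, axes=[0]),
                    ),
                )
                lo = int(rng.integers(0, n))
                hi = int(rng.integers(lo, n + 1))
                mapped = map_selection(rel, Selection.axes((slice(lo, hi),)))
                assert mapped.kind == "axes"
                sel0 = mapped.selectors[0]
                assert isinstance(sel0, slice) or sel0 == ()


class TestIndexMapRelationships:
    def test_fixture_without_user_leg_has_three_attributes(self, image_file):
        attrs = [
            k
            for obj in ("source_image", "index_map")
            for k in image_file[obj].attrs
            if k.startswith(RELATIONSHIP_PREFIX)
        ]
        assert len(attrs) == 3
        postfixes = {k.rsplit("_IMR_", 1)[1] for k in attrs}
        assert postfixes == {"SOURCE_TO_MAP", "MAP_TO_SOURCE", "MAP_TO_TARGET"}

    def test_with_user_leg_postfix_set_complete(self, tmp_path, small_image_params):
        from dataclasses import replace

        from managedh5 import generate_image_scaling_fixture

        params = replace(small_image_params, include_user_leg=True)
        h5 = generate_image_scaling_fixture(params, str(tmp_path / "u.h5"))
        attrs = [
            k
            for obj in ("source_image", "index_map")
            for k in h5[obj].attrs
            if k.startswith(RELATIONSHIP_PREFIX)
        ]
        assert len(attrs) == 4
        assert {k.rsplit("_IMR_", 1)[1] for k in attrs} == set(IMR_POSTFIXES)
        h5.close()

    def test_identity_map_maps_identically(self):
        with memfile() as f:
            a = f.create_dataset("a", data=np.arange(8))
            m = f.create_dataset("m", data=np.arange(8))
            b = f.create_dataset("b", data=np.arange(8) * 2)
            imr = create_index_map_relationship(a, m, b, "ident")
            mapped = imr_map(imr, "SOURCE_TO_TARGET", Selection.axes((slice(2, 5),)))
            assert mapped == Selection.axes((slice(2, 5),))

    def test_block_mapping_coordinates(self, image_file, small_image_params):
        p = small_image_params
        scan = get_index_map_relationships(image_file["/"])
        imr = scan.bundles[0]
        i, j = 3, 7
        mapped = imr_map(imr, "MAP_TO_TARGET", Selection.axes((i, j)))
        f = p.factor
        expected = {
            (j * f + r, i * f + c) for r in range(f) for c in range(f)
        }
        assert set(mapped.point_list) == expected

    def test_inverse_order_legs_compose_to_identity(self, image_file):
        imr = get_index_map_relationships(image_file["/"]).bundles[0]
        sel = Selection.axes((slice(1, 4), (0, 5, 2)))
        mid = imr_map(imr, "SOURCE_TO_MAP", sel)
        back = imr_map(imr, "MAP_TO_SOURCE", mid)
        assert back == sel

    def test_composition_law(self, image_file):
        imr = get_index_map_relationships(image_file["/"]).bundles[0]
        sel = Selection.axes(((1, 3), slice(0, 2)))
        composed = imr_map(imr, "SOURCE_TO_TARGET", sel)
        manual = map_selection(
            imr.leg("MAP_TO_TARGET"), map_selection(imr.leg("SOURCE_TO_MAP"), sel)
        )
        from managedh5.relationships import _canonical

        assert composed == _canonical(manual)

    def test_missing_leg_lookup_error(self, image_file):
        imr = get_index_map_relationships(image_file["/"]).bundles[0]
        with pytest.raises(ObjectLookupError):
            imr.leg("NOT_A_LEG")
        del imr.legs["MAP_TO_SOURCE"]
        with pytest.raises(ObjectLookupError):
            imr_map(imr, "MAP_TO_SOURCE", Selection.axes((0, 0)))

    def test_getitem_sugar(self, image_file, small_image_params):
        imr = get_index_map_relationships(image_file["/"]).bundles[0]
        mapped = imr["MAP_TO_TARGET"][2, 2]
        assert len(mapped.point_list) == small_image_params.factor ** 2

    def test_rollback_on_leg_failure(self):
        with memfile() as f:
            a = f.create_dataset("a", data=np.arange(4))
            m = f.create_dataset("m", data=np.arange(4).astype(float))  # not int
            b = f.create_dataset("b", data=np.arange(4))
            with pytest.raises(RelationshipError):
                create_index_map_relationship(a, m, b, "bad")
            assert not [k for k in a.attrs if k.startswith(RELATIONSHIP_PREFIX)]
            assert not [k for k in m.attrs if k.startswith(RELATIONSHIP_PREFIX)]

    def test_scan_finds_exactly_one_bundle(self, image_file):
        scan = get_index_map_relationships(image_file["/"])
        assert len(scan) == 1
        assert scan.findings == []

    def test_dropped_leg_reports_incomplete_bundle(self, image_path):
        from managedh5 import inject_violation

        inject_violation(image_path, "drop_imr_leg")
        with h5py.File(image_path, "r") as h5:
            scan = get_index_map_relationships(h5["/"])
        assert len(scan) == 0
        assert len(scan.findings) == 1
        assert scan.findings[0]["rule"] == "incomplete-imr-bundle"
        assert scan.findings[0]["missing_legs"] == ["MAP_TO_TARGET"]

    def test_plain_relationships_yield_no_bundles(self):
        with memfile() as f:
            _simple_rel(f, "order", np.arange(3), np.arange(3))
            scan = get_index_map_relationships(f["/"])
            assert len(scan) == 0 and scan.findings == []


class TestNtoM:
    def _random_imr(self, f, rng, uid):
        """Random 1-D N-to-M map with fill sentinels and shared targets."""
        n_src = int(rng.integers(1, 20))
        n_tgt = int(rng.integers(1, 20))
        k = int(rng.integers(1, 5))
        m_data = rng.integers(0, n_tgt, size=(n_src, k))
        mask = rng.random((n_src, k)) < 0.3
        m_data[mask] = -1
        a = f.create_dataset(f"na{uid}", data=rng.random(n_src))
        m = f.create_dataset(f"nm{uid}", data=m_data)
        b = f.create_dataset(f"nb{uid}", data=rng.random(n_tgt))
        return create_index_map_relationship(a, m, b, f"n2m{uid}"), m_data

    def test_every_stored_pair_recovered(self):
        rng = np.random.default_rng(21)
        with memfile() as f:
            for trial in range(25):
                imr, m_data = self._random_imr(f, rng, trial)
                pairs = oracle_imr_pairs(m_data)
                for i in range(m_data.shape[0]):
                    mapped = imr_map(imr, "SOURCE_TO_TARGET", Selection.axes((i,)))
                    got = {
                        ((i,), (t,)) for t in selection_indices(mapped, None)
                    }
                    expected = {p for p in pairs if p[0] == (i,)}
                    assert got == expected

    def test_composition_law_on_random_maps(self):
        rng = np.random.default_rng(22)
        with memfile() as f:
            for trial in range(25):
                imr, m_data = self._random_imr(f, rng, trial)
                n_src = m_data.shape[0]
                sel = random_selection(rng, n_src)
                composed = imr_map(imr, "SOURCE_TO_TARGET", sel)
                from managedh5.relationships import _canonical

                manual = _canonical(
                    map_selection(
                        imr.leg("MAP_TO_TARGET"),
                        map_selection(imr.leg("SOURCE_TO_MAP"), sel),
                    )
                )
                assert composed == manual

    def test_results_deduplicated_ascending(self):
        with memfile() as f:
            a = f.create_dataset("a", data=np.arange(3))
            m = f.create_dataset("m", data=np.array([[5, 5, 2], [2, -1, 5], [0, 0, 0]]))
            b = f.create_dataset("b", data=np.arange(6))
            imr = create_index_map_relationship(a, m, b, "dup")
            mapped = imr_map(imr, "SOURCE_TO_TARGET", Selection.axes((slice(0, 2),)))
            assert selection_indices(mapped, 6) == [2, 5]
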