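"""Deterministic synthetic-data generators and violation injection.

Everything here is a pure function of its parameters and seed, so every
other module can be exercised without any external data: a synthetic
multi-electrode session file (grid + polytrode devices, raw and processed
voltage groups, a stimulus schedule with relationships into the time scale)
and an image-scaling fixture realizing an index-map relationship between a
low-resolution source image and a higher-resolution target.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import h5py
import numpy as np

from .ephys import (
    create_collection,
    create_ephys,
    create_processed_ephys,
    create_session_file,
)
from .errors import ViolationError
from .managed import (
    MANAGED_TYPE_ATTR,
    create_external_managed_object,
    find_managed_objects,
)
from .registry import DEFAULT_REGISTRY
from .relationships import (
    IMR_POSTFIXES,
    RELATIONSHIP_PREFIX,
    RelationshipDescriptor,
    RelationshipTarget,
    create_index_map_relationship,
    create_relationship_attribute,
)

__all__ = [
    "SessionParams",
    "ImageMapParams",
    "generate_ephys_session",
    "generate_image_scaling_fixture",
    "inject_violation",
    "InjectedViolation",
    "VIOLATION_KINDS",
]


@dataclass
class SessionParams:
    """Parameters of the synthetic two-device recording session."""

    n_grid_electrodes: int = 16
    n_poly_electrodes: int = 4
    sampling_rate: float = 1000.0  # Hz; kept small so fixtures stay light
    frequencies_khz: Sequence[float] = (0.5, 32.0)
    attenuations_db: Sequence[float] = (0.0, -70.0)
    repetitions: int = 20
    stimulus_duration_ms: float = 300.0
    duration_ms: Optional[float] = None  # derived from the schedule if None
    n_bands: int = 2
    seed: int = 0
    external_processed: bool = False  # store processed groups in linked files

    @property
    def n_conditions(self) -> int:
        return len(self.frequencies_khz) * len(self.attenuations_db)

    @property
    def n_stimuli(self) -> int:
        return self.n_conditions * self.repetitions


@dataclass
class ImageMapParams:
    """Parameters of the image-scaling index-map fixture.

    The source image axis 0 maps to target axis 1 and vice versa; the target
    shape is the swapped source shape times the scale factor.
    """

    rows: int = 120
    cols: int = 122
    factor: int = 5
    seed: int = 0
    include_user_leg: bool = False


def _device_signal(rng, n_electrodes, n_samples, rate):
    """Per-electrode sinusoid (frequency varying by electrode) plus Gaussian
    noise; amplitudes ~1e-4 V.  No physiological claim."""
    t = np.arange(n_samples) / rate
    freqs = 5.0 + 3.0 * np.arange(n_electrodes)
    signal = 1e-4 * np.sin(2 * np.pi * freqs[:, None] * t[None, :])
    noise = 2e-5 * rng.standard_normal((n_electrodes, n_samples))
    return signal + noise


def generate_ephys_session(params: SessionParams, path: str):
    """Generate a compliant synthetic session file.

    Layout: two device collections (grid, polytrode) under internal data,
    one raw and one processed ephys group per device, and a stimulus group
    under external data whose onset datasets carry ``indexes`` and
    ``indexes_values`` relationships into the grid time scale.  All stored
    values are a pure function of (params, seed).
    """
    rng = np.random.default_rng(params.seed)
    stim_samples = int(round(params.stimulus_duration_ms * params.sampling_rate / 1000.0))
    n_stim = params.n_stimuli
    duration_ms = (
        params.duration_ms
        if params.duration_ms is not None
        else (n_stim + 1) * params.stimulus_duration_ms
    )
    n_samples = int(round(duration_ms * params.sampling_rate / 1000.0))

    session = create_session_file(path, overwrite=True)
    internal = session["/data/internal"]
    external = session["/data/external"]

    devices = [
        ("grid", params.n_grid_electrodes),
        ("polytrode", params.n_poly_electrodes),
    ]
    band_centers = 30.0 + 50.0 * np.arange(params.n_bands)
    for dev_name, n_el in devices:
        coll = create_collection(internal, f"collection_{dev_name}")
        raw = _device_signal(rng, n_el, n_samples, params.sampling_rate)
        ephys = create_ephys(
            coll,
            f"ephys_data_{dev_name}",
            raw=raw,
            sampling_rate=params.sampling_rate,
            electrode_ids=np.arange(n_el),
            anatomy=(
                np.array([f"A1_{i % 4}" for i in range(n_el)], dtype="S"),
                np.arange(n_el) % 4,
            ),
        )
        processed = np.stack(
            [np.abs(raw) * (b / 100.0) for b in band_centers], axis=2
        ) + 1e-6 * rng.standard_normal((n_el, n_samples, params.n_bands))
        payload = dict(
            data=processed,
            sampling_rate=params.sampling_rate,
            electrode_ids=np.arange(n_el),
            band_values=band_centers,
            raw_path=ephys.path,
        )
        if params.external_processed:
            proc = create_external_managed_object(
                coll.obj,
                "BrainDataEphysProcessed",
                external_path=str(path) + f".{dev_name}_processed.h5",
                name=f"ephys_processed_{dev_name}",
                payload={k: v for k, v in payload.items() if k != "raw_path"},
            )
            # cross-file links back to the raw group; the session file is
            # still open for writing, so creation must tolerate deferred
            # target resolution
            session_rel = os.path.basename(str(path))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                create_relationship_attribute(
                    proc.obj["electrode_id"],
                    "space_order_to_source",
                    RelationshipDescriptor(
                        relationship_type="order",
                        description="Electrodes are ordered as in the source "
                        "recording.",
                        source_axes=[0],
                        target=RelationshipTarget(
                            location={
                                "file": session_rel,
                                "path": ephys.path + "/electrode_id",
                            },
                            axes=[0],
                        ),
                    ),
                    allow_dangling=True,
                )
                create_relationship_attribute(
                    proc.obj["time"],
                    "time_alignment_to_source",
                    RelationshipDescriptor(
                        relationship_type="shared_ascending_encoding",
                        description="Both time scales encode milliseconds in "
                        "ascending order.",
                        source_axes=[0],
                        target=RelationshipTarget(
                            location={
                                "file": session_rel,
                                "path": ephys.path + "/time",
                            },
                            axes=[0],
                        ),
                    ),
                    allow_dangling=True,
                )
        else:
            create_processed_ephys(
                coll,
                f"ephys_processed_{dev_name}",
                raw_link=ephys,
                **{k: v for k, v in payload.items() if k != "raw_path"},
            )

    # stimulus schedule: conditions in row-major (frequency x attenuation)
    # order cycling over repetitions, onsets evenly spaced
    conditions = [
        (f, a) for f in params.frequencies_khz for a in params.attenuations_db
    ]
    order = np.tile(np.arange(len(conditions)), params.repetitions)
    onset_samples = (np.arange(n_stim) * stim_samples).astype(np.int64)
    grid_time = session["/data/internal/collection_grid/ephys_data_grid/time"]
    onset_times = grid_time[()][onset_samples]

    stim = external.create_group("stimulus")
    stim.create_dataset("onset_sample", data=onset_samples)
    stim.create_dataset("onset_time", data=onset_times)
    stim.create_dataset(
        "frequency_khz", data=np.array([conditions[i][0] for i in order])
    )
    stim.create_dataset(
        "attenuation_db", data=np.array([conditions[i][1] for i in order])
    )
    stim.create_dataset(
        "duration_ms", data=np.full(n_stim, params.stimulus_duration_ms)
    )
    create_relationship_attribute(
        stim["onset_sample"],
        "onsets_index_time",
        RelationshipDescriptor(
            relationship_type="indexes",
            description="Onset sample indices point into the grid time scale.",
            source_axes=[0],
            target=RelationshipTarget(location=grid_time.name, axes=[0]),
        ),
    )
    create_relationship_attribute(
        stim["onset_time"],
        "onsets_select_time",
        RelationshipDescriptor(
            relationship_type="indexes_values",
            description="Onset times select matching values in the grid time "
            "scale.",
            source_axes=[0],
            target=RelationshipTarget(location=grid_time.name, axes=[0]),
        ),
    )
    session.obj.file.flush()
    return session


def generate_image_scaling_fixture(params: ImageMapParams, path: str):
    """Generate the image-scaling index-map fixture.

    Stores a source image A of shape (rows, cols), a target image B of shape
    (cols*factor, rows*factor) — source axis 0 maps to target axis 1 and
    vice versa — and a 4-dimensional index map M of shape
    (rows, cols, 2, factor**2): two spatial axes, an index axis of length 2
    (row/col pairs into B), and a stacking axis listing every corresponding
    target pixel.  The full relationship chain is created in one call.

    Returns an open file handle (caller closes).
    """
    rng = np.random.default_rng(params.seed)
    rows, cols, f = params.rows, params.cols, params.factor
    a = rng.random((rows, cols))
    b = np.empty((cols * f, rows * f))
    for i in range(rows):
        for j in range(cols):
            b[j * f:(j + 1) * f, i * f:(i + 1) * f] = a[i, j]

    k = np.arange(f * f)
    m = np.empty((rows, cols, 2, f * f), dtype=np.int64)
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    m[:, :, 0, :] = jj[:, :, None] * f + (k // f)[None, None, :]
    m[:, :, 1, :] = ii[:, :, None] * f + (k % f)[None, None, :]

    h5 = h5py.File(path, "w")
    src = h5.create_dataset("source_image", data=a)
    tgt = h5.create_dataset("target_image", data=b)
    imap = h5.create_dataset("index_map", data=m)
    create_index_map_relationship(
        src,
        imap,
        tgt,
        base_name="image_map",
        user_properties=(
            {"method": "block upscaling", "factor": f}
            if params.include_user_leg
            else None
        ),
    )
    h5.flush()
    return h5


VIOLATION_KINDS = (
    "delete_required",
    "wrong_attribute_value",
    "scale_length_mismatch",
    "broken_external_link",
    "drop_imr_leg",
)


@dataclass
class InjectedViolation:
    """What was mutated and what the verifier must flag."""

    kind: str
    path: str  # the path of the mutated object
    rule: str  # the verification rule expected to fire
    detail: dict = field(default_factory=dict)


def _first_ephys_group(h5):
    hits = find_managed_objects(h5, "BrainDataEphys", registry=DEFAULT_REGISTRY)
    if not hits:
        raise ViolationError("file contains no ephys group")
    return hits[0]


def inject_violation(path: str, kind: str) -> InjectedViolation:
    """Apply exactly one compliance violation to the file at ``path``.

    Returns the mutated object's path and the rule the verifier must flag.
    Raises :class:`ViolationError` when the kind is inapplicable to the file.
    """
    if kind not in VIOLATION_KINDS:
        raise ViolationError(f"unknown violation kind {kind!r}")
    with h5py.File(path, "r+") as h5:
        if kind == "delete_required":
            eph = _first_ephys_group(h5)
            target = eph.path + "/raw_data"
            del eph.obj["raw_data"]
            return InjectedViolation(kind, target, "required-dataset")
        if kind == "wrong_attribute_value":
            eph = _first_ephys_group(h5)
            eph.obj["raw_data"].attrs["unit"] = "mV"
            return InjectedViolation(
                kind, eph.path + "/raw_data", "fixed-attribute-value"
            )
        if kind == "scale_length_mismatch":
            eph = _first_ephys_group(h5)
            obj = eph.obj
            raw = obj["raw_data"]
            old = obj["electrode_id"][()]
            del obj["electrode_id"]
            bad = obj.create_dataset(
                "electrode_id", data=np.concatenate([old, [old[-1] + 1]])
            )
            bad.make_scale("space")
            raw.dims[0].attach_scale(bad)
            return InjectedViolation(
                kind, eph.path + "/raw_data", "dimension-scale-length"
            )
        if kind == "broken_external_link":
            found = _find_external_link(h5["/"])
            if found is None:
                raise ViolationError("file contains no external link")
            parent_path, name = found
            parent = h5[parent_path] if parent_path else h5["/"]
            del parent[name]
            parent[name] = h5py.ExternalLink("nonexistent_file.h5", "/missing")
            return InjectedViolation(
                kind, (parent_path or "") + "/" + name, "broken-link"
            )
        if kind == "drop_imr_leg":
            for obj_path, attr_name in _find_imr_attrs(h5["/"]):
                if attr_name.endswith(IMR_POSTFIXES["MAP_TO_TARGET"]):
                    del h5[obj_path].attrs[attr_name]
                    return InjectedViolation(
                        kind, obj_path, "incomplete-imr-bundle",
                        detail={"attribute": attr_name},
                    )
            raise ViolationError("file contains no index-map relationship")
    raise AssertionError("unreachable")


def _find_external_link(root):
    stack = [("", root)]
    while stack:
        gpath, g = stack.pop()
        for name in sorted(g):
            link = g.get(name, getlink=True)
            if isinstance(link, h5py.ExternalLink):
                return gpath, name
            try:
                child = g[name]
            except KeyError:
                continue
            if isinstance(child, h5py.Group):
                stack.append((gpath + "/" + name, child))
    return None


def _find_imr_attrs(root):
    out = []
    stack = [("/", root)]
    while stack:
        gpath, obj = stack.pop()
        for attr_name in obj.attrs:
            if attr_name.startswith(RELATIONSHIP_PREFIX) and "_IMR_" in attr_name:
                out.append((gpath, attr_name))
        if isinstance(obj, h5py.Group):
            for name in sorted(obj):
                try:
                    child = obj[name]
                except KeyError:
                    continue
                stack.append((gpath.rstrip("/") + "/" + name, child))
    return out
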