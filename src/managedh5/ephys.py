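"""Application format for electrophysiology recordings.

Managed types registered by this module:

* ``BrainDataFile`` — session file with the ``/data/{internal,external}`` and
  ``/descriptors/{static,dynamic}`` hierarchy;
* ``BrainDataCollection`` — grouping of device data under internal/external;
* ``BrainDataEphys`` — managed group holding a 2-D space x time voltage
  array (``raw_data``, unit Volt) with electrode-id and time dimension
  scales and a stored sampling rate;
* ``BrainDataEphysProcessed`` — extension of the ephys group to 3-D
  space x time x band arrays with an additional band scale.

Order relationships between every built-in dimension scale and the primary
dataset are created automatically; time scales are generated from the
sampling rate (milliseconds, ``t_k = start + 1000*k/rate``) when not
supplied.  Auto-expand mode creates the time axis empty and extendible so
recordings can be appended as they are acquired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import h5py
import numpy as np

from .errors import AutoExpandError, CreationError, ObjectLookupError
from .managed import (
    ManagedObjectHandle,
    create_managed_file,
    create_managed_object,
    wrap_managed_object,
)
from .registry import DEFAULT_REGISTRY
from .relationships import (
    RelationshipDescriptor,
    RelationshipTarget,
    create_relationship_attribute,
)
from .selection import Selection
from .spec import (
    AttributeSpec,
    DatasetSpec,
    DimensionSpec,
    FileSpec,
    GroupSpec,
    ManagedRef,
    RelationshipSpec,
)

__all__ = [
    "EPHYS_PREFIX",
    "PROCESSED_PREFIX",
    "COLLECTION_PREFIX",
    "DimensionScaleRecord",
    "EphysGroup",
    "ProcessedEphysGroup",
    "create_session_file",
    "create_collection",
    "create_ephys",
    "create_processed_ephys",
    "append_recordings",
    "add_dimension_scale",
    "get_dimension_scales",
    "read",
    "aux",
]

EPHYS_PREFIX = "ephys_data_"
PROCESSED_PREFIX = "ephys_processed_"
COLLECTION_PREFIX = "collection_"

_AUTO_EXPAND_ATTR = "AUTO_EXPAND"
_START_TIME_ATTR = "start_time"
_TIME_CHUNK = 1024


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


def _scale_dataset_spec(name, description, optional=False):
    ds = DatasetSpec(dataset=name, optional=optional, description=description)
    if not optional:
        ds.add_relationship(
            RelationshipSpec(
                attribute=f"{name}_order_to_raw_data",
                relationship_type="order",
                description=f"Ordering of {name!r} matches the described axis "
                "of raw_data.",
                source_axes=[0],
                target=RelationshipTarget(location="raw_data", axes=[0]),
            )
        )
    return ds


def _ephys_group_spec(prefix=EPHYS_PREFIX, with_band=False):
    g = GroupSpec(
        group=None,
        prefix=prefix,
        description="Managed group for storage of raw Ephys recordings.",
    )
    raw = DatasetSpec(
        dataset="raw_data",
        prefix=None,
        optional=False,
        primary=True,
        description="Dataset with the Ephys recordings data",
    )
    raw.add_attribute(AttributeSpec(attribute="unit", prefix=None, value="Volt"))
    raw.add_dimension(
        DimensionSpec(
            name="space",
            unit="id",
            dataset="electrode_id",
            axis=0,
            description="Id of the recording electrode",
        )
    )
    raw.add_dimension(
        DimensionSpec(
            name="time",
            unit="ms",
            dataset="time",
            axis=1,
            description="Sample time in milliseconds",
        )
    )
    if with_band:
        raw.add_dimension(
            DimensionSpec(
                name="band",
                unit="Hz",
                dataset="band",
                axis=2,
                description="Center frequency of the processing band",
            )
        )
    g.add_dataset(raw, "raw_data")
    g.add_dataset(
        DatasetSpec(
            dataset="sampling_rate",
            optional=False,
            description="Sampling rate of the recording in Hz",
        ),
        "sampling_rate",
    )
    g.add_dataset(
        _scale_dataset_spec("electrode_id", "Id of the recording electrode"),
        "electrode_id",
    )
    g.add_dataset(
        _scale_dataset_spec("time", "Sample time in milliseconds"), "time"
    )
    if with_band:
        g.add_dataset(
            _scale_dataset_spec("band", "Center frequency of the band"), "band"
        )
    g.add_dataset(
        DatasetSpec(
            dataset="anatomy_name",
            optional=True,
            description="Anatomical name of each electrode location",
        ),
        "anatomy_name",
    )
    g.add_dataset(
        DatasetSpec(
            dataset="anatomy_id",
            optional=True,
            description="Integer id of each electrode's anatomical region",
        ),
        "anatomy_id",
    )
    return g


def _ephys_spec():
    return _ephys_group_spec()


def _processed_spec():
    return _ephys_group_spec(prefix=PROCESSED_PREFIX, with_band=True)


def _collection_spec():
    g = GroupSpec(
        group=None,
        prefix=COLLECTION_PREFIX,
        description="Collection grouping data belonging to one device.",
    )
    g.add_managed(ManagedRef(managed_type="BrainDataEphys", optional=True))
    return g


def _session_file_spec():
    spec = FileSpec(description="Managed electrophysiology session file.")
    internal = GroupSpec(
        group="internal",
        description="Data collected inside the brain.",
    )
    internal.add_managed(ManagedRef(managed_type="BrainDataCollection", optional=True))
    internal.add_managed(ManagedRef(managed_type="BrainDataEphys", optional=True))
    external = GroupSpec(
        group="external",
        description="Data collected external to the subject.",
    )
    data = GroupSpec(group="data", description="Raw and processed data.")
    data.add_group(internal, "internal")
    data.add_group(external, "external")
    descriptors = GroupSpec(group="descriptors", description="Global metadata.")
    descriptors.add_group(
        GroupSpec(group="static", description="Static metadata."), "static"
    )
    descriptors.add_group(
        GroupSpec(group="dynamic", description="Dynamic metadata."), "dynamic"
    )
    spec.add_group(data, "data")
    spec.add_group(descriptors, "descriptors")
    return spec


# ---------------------------------------------------------------------------
# Dimension scales
# ---------------------------------------------------------------------------


@dataclass
class DimensionScaleRecord:
    """The five-field description of one dimension scale."""

    name: str
    unit: str
    data: np.ndarray
    description: str
    axis: int
    dataset: str = ""


def _attach_scale(group, raw, axis, scale_name, dataset_name, unit, data,
                  description, resizable=False):
    if dataset_name in group:
        raise CreationError(f"scale dataset {dataset_name!r} already exists")
    data = np.asarray(data)
    if data.shape[0] != raw.shape[axis]:
        raise CreationError(
            f"scale {dataset_name!r} has length {data.shape[0]} but axis "
            f"{axis} has extent {raw.shape[axis]}"
        )
    kwargs = {}
    if resizable:
        kwargs = {"maxshape": (None,), "chunks": (_TIME_CHUNK,)}
    ds = group.create_dataset(dataset_name, data=data, **kwargs)
    ds.attrs["unit"] = unit
    ds.attrs["description"] = description
    ds.attrs["axis"] = axis
    ds.make_scale(scale_name)
    raw.dims[axis].attach_scale(ds)
    return ds


def _auto_order_relationship(group, scale_dataset_name):
    create_relationship_attribute(
        group[scale_dataset_name],
        f"{scale_dataset_name}_order_to_raw_data",
        RelationshipDescriptor(
            relationship_type="order",
            description=f"Ordering of {scale_dataset_name!r} matches the "
            "described axis of raw_data.",
            source_axes=[0],
            target=RelationshipTarget(
                location=group["raw_data"].name, axes=[0]
            ),
        ),
    )


def _time_values(start_time, rate, k0, k1):
    return start_time + 1000.0 * np.arange(k0, k1, dtype=np.float64) / rate


def _populate_voltage_group(
    obj,
    data,
    sampling_rate,
    electrode_ids,
    band_values=None,
    band_unit="Hz",
    start_time=0.0,
    anatomy=None,
    auto_expand=False,
    unit="Volt",
    raw_path=None,
):
    rank = 2 if band_values is None else 3
    electrode_ids = np.asarray(electrode_ids)
    n = electrode_ids.shape[0]
    if sampling_rate is None or sampling_rate <= 0:
        raise CreationError("sampling_rate must be positive")
    if data is not None:
        data = np.asarray(data)
        if data.ndim != rank:
            raise CreationError(f"expected rank-{rank} data, got rank {data.ndim}")
        if data.shape[0] != n:
            raise CreationError(
                f"electrode_ids length {n} does not match space extent "
                f"{data.shape[0]}"
            )
        if rank == 3:
            if band_values is None or len(band_values) != data.shape[2]:
                raise CreationError(
                    "band scale length does not match the band extent"
                )
    elif not auto_expand:
        raise CreationError("data is required unless auto_expand is set")

    t0 = 0 if data is None else data.shape[1]
    if auto_expand and data is not None:
        raise CreationError("auto_expand groups start empty; append data instead")

    shape = (n, t0) if rank == 2 else (n, t0, len(band_values))
    kwargs = {}
    if auto_expand:
        maxshape = (n, None) if rank == 2 else (n, None, len(band_values))
        chunks = (n, _TIME_CHUNK) if rank == 2 else (n, _TIME_CHUNK, len(band_values))
        kwargs = {"maxshape": maxshape, "chunks": chunks}
    raw = obj.create_dataset("raw_data", shape=shape, dtype="f8", **kwargs)
    if data is not None:
        raw[...] = data
    raw.attrs["unit"] = unit
    obj.create_dataset("sampling_rate", data=float(sampling_rate))
    obj.attrs[_AUTO_EXPAND_ATTR] = bool(auto_expand)

    _attach_scale(
        obj, raw, 0, "space", "electrode_id", "id", electrode_ids,
        "Id of the recording electrode",
    )
    time = _attach_scale(
        obj, raw, 1, "time", "time", "ms",
        _time_values(start_time, sampling_rate, 0, t0),
        "Sample time in milliseconds", resizable=auto_expand,
    )
    time.attrs[_START_TIME_ATTR] = float(start_time)
    auto_scales = ["electrode_id", "time"]
    if rank == 3:
        _attach_scale(
            obj, raw, 2, "band", "band", band_unit, np.asarray(band_values),
            "Center frequency of the processing band",
        )
        auto_scales.append("band")
    if anatomy is not None:
        names, ids = anatomy
        _attach_scale(
            obj, raw, 0, "anatomy_name", "anatomy_name", "name", np.asarray(names),
            "Anatomical name of each electrode location",
        )
        _attach_scale(
            obj, raw, 0, "anatomy_id", "anatomy_id", "id", np.asarray(ids),
            "Integer id of each electrode's anatomical region",
        )
        auto_scales += ["anatomy_name", "anatomy_id"]
    for ds_name in auto_scales:
        _auto_order_relationship(obj, ds_name)

    if raw_path is not None:
        raw_group = obj.file[raw_path]
        create_relationship_attribute(
            obj["electrode_id"],
            "space_order_to_source",
            RelationshipDescriptor(
                relationship_type="order",
                description="Electrodes are ordered as in the source recording.",
                source_axes=[0],
                target=RelationshipTarget(
                    location=raw_group["electrode_id"].name, axes=[0]
                ),
            ),
        )
        create_relationship_attribute(
            obj["time"],
            "time_alignment_to_source",
            RelationshipDescriptor(
                relationship_type="shared_ascending_encoding",
                description="Both time scales encode milliseconds in ascending "
                "order.",
                source_axes=[0],
                target=RelationshipTarget(
                    location=raw_group["time"].name, axes=[0]
                ),
            ),
        )


def _populate_ephys(obj, raw=None, sampling_rate=None, electrode_ids=None,
                    start_time=0.0, anatomy=None, auto_expand=False):
    _populate_voltage_group(
        obj, raw, sampling_rate, electrode_ids,
        start_time=start_time, anatomy=anatomy, auto_expand=auto_expand,
    )


def _populate_processed(obj, data=None, sampling_rate=None, electrode_ids=None,
                        band_values=None, band_unit="Hz", start_time=0.0,
                        anatomy=None, auto_expand=False, raw_path=None):
    _populate_voltage_group(
        obj, data, sampling_rate, electrode_ids, band_values=band_values,
        band_unit=band_unit, start_time=start_time, anatomy=anatomy,
        auto_expand=auto_expand, raw_path=raw_path,
    )


def _populate_session(root):
    data = root.create_group("data")
    data.create_group("internal")
    data.create_group("external")
    desc = root.create_group("descriptors")
    desc.create_group("static")
    desc.create_group("dynamic")


# ---------------------------------------------------------------------------
# Handles
# ---------------------------------------------------------------------------


class EphysGroup(ManagedObjectHandle):
    """Handle onto a stored ephys managed group."""

    @property
    def raw(self) -> h5py.Dataset:
        return self.obj["raw_data"]

    @property
    def sampling_rate(self) -> float:
        return float(self.obj["sampling_rate"][()])

    @property
    def auto_expand(self) -> bool:
        return bool(self.obj.attrs.get(_AUTO_EXPAND_ATTR, False))

    def read(self, selection=None):
        return read(self, selection)

    def aux(self, key):
        return aux(self, key)

    def append(self, block, scale_values=None) -> int:
        return append_recordings(self, block, scale_values)

    def add_dimension_scale(self, axis, name, unit, data, description=""):
        return add_dimension_scale(self, axis, name, unit, data, description)

    def get_dimension_scales(self, axis=None):
        return get_dimension_scales(self, axis)


class ProcessedEphysGroup(EphysGroup):
    """Handle onto a processed (space x time x band) ephys group."""

    @property
    def data(self) -> h5py.Dataset:
        # the 3-D array is stored under the inherited primary-dataset name
        return self.obj["raw_data"]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def create_session_file(path, overwrite=False, registry=None):
    """Create a session file with the standard data/descriptor hierarchy."""
    return create_managed_file(
        path, "BrainDataFile", overwrite=overwrite,
        registry=registry or DEFAULT_REGISTRY,
    )


def create_collection(parent, name, registry=None):
    """Create a device-data collection under a data group."""
    return create_managed_object(
        parent, "BrainDataCollection", name=name,
        registry=registry or DEFAULT_REGISTRY,
    )


def create_ephys(
    parent,
    name,
    raw=None,
    sampling_rate=None,
    electrode_ids=None,
    start_time=0.0,
    anatomy=None,
    auto_expand=False,
    registry=None,
) -> EphysGroup:
    """Create a managed ephys group holding a 2-D space x time voltage array.

    The time scale is generated from the sampling rate in milliseconds.  With
    ``auto_expand`` the time axis starts empty and grows via
    :func:`append_recordings`.
    """
    return create_managed_object(
        parent,
        "BrainDataEphys",
        name=name,
        payload=dict(
            raw=raw,
            sampling_rate=sampling_rate,
            electrode_ids=electrode_ids,
            start_time=start_time,
            anatomy=anatomy,
            auto_expand=auto_expand,
        ),
        registry=registry or DEFAULT_REGISTRY,
    )


def create_processed_ephys(
    parent,
    name,
    data=None,
    sampling_rate=None,
    electrode_ids=None,
    band_values=None,
    band_unit="Hz",
    start_time=0.0,
    raw_link=None,
    registry=None,
) -> ProcessedEphysGroup:
    """Create a processed ephys group (space x time x band).

    When ``raw_link`` names the originating raw group, an order relationship
    on the shared space axis and a shared-ascending-encoding relationship
    between the two time scales are created automatically.
    """
    raw_path = None
    if raw_link is not None:
        raw_path = raw_link.path if isinstance(raw_link, ManagedObjectHandle) else (
            raw_link.name if isinstance(raw_link, h5py.Group) else str(raw_link)
        )
    return create_managed_object(
        parent,
        "BrainDataEphysProcessed",
        name=name,
        payload=dict(
            data=data,
            sampling_rate=sampling_rate,
            electrode_ids=electrode_ids,
            band_values=band_values,
            band_unit=band_unit,
            start_time=start_time,
            raw_path=raw_path,
        ),
        registry=registry or DEFAULT_REGISTRY,
    )


def append_recordings(ephys, block, scale_values=None) -> int:
    """Append a space x t_new block to an auto-expand ephys group.

    Grows ``raw_data`` and every time-axis scale consistently and returns the
    new time extent.  Custom time-axis scales require their extension values
    in ``scale_values`` (dataset name -> values).
    """
    obj = ephys.obj if isinstance(ephys, ManagedObjectHandle) else ephys
    if not bool(obj.attrs.get(_AUTO_EXPAND_ATTR, False)):
        raise AutoExpandError(
            f"group {obj.name!r} was not created in auto-expand mode"
        )
    raw = obj["raw_data"]
    block = np.asarray(block)
    if block.ndim != raw.ndim:
        raise CreationError(
            f"block rank {block.ndim} does not match data rank {raw.ndim}"
        )
    if block.shape[0] != raw.shape[0]:
        raise CreationError(
            f"block space extent {block.shape[0]} does not match "
            f"{raw.shape[0]}"
        )
    t_new = block.shape[1]
    old = raw.shape[1]
    if t_new == 0:
        return old
    new_shape = list(raw.shape)
    new_shape[1] = old + t_new
    raw.resize(tuple(new_shape))
    raw[:, old:old + t_new, ...] = block

    rate = float(obj["sampling_rate"][()])
    scale_values = scale_values or {}
    for _, scale in list(obj["raw_data"].dims[1].items()):
        ds_name = scale.name.rsplit("/", 1)[-1]
        scale.resize((old + t_new,))
        if ds_name == "time":
            start = float(scale.attrs.get(_START_TIME_ATTR, 0.0))
            scale[old:] = _time_values(start, rate, old, old + t_new)
        elif ds_name in scale_values:
            vals = np.asarray(scale_values[ds_name])
            if vals.shape[0] != t_new:
                raise CreationError(
                    f"extension for scale {ds_name!r} has length "
                    f"{vals.shape[0]}, expected {t_new}"
                )
            scale[old:] = vals
        else:
            raise AutoExpandError(
                f"no extension values supplied for custom time-axis scale "
                f"{ds_name!r}"
            )
    return old + t_new


def add_dimension_scale(ephys, axis, name, unit, data, description="") -> DimensionScaleRecord:
    """Attach a custom dimension scale to one axis of the primary dataset."""
    obj = ephys.obj if isinstance(ephys, ManagedObjectHandle) else ephys
    raw = obj["raw_data"]
    if axis < 0 or axis >= raw.ndim:
        raise CreationError(f"axis {axis} out of range for rank {raw.ndim}")
    existing = [n for n, _ in raw.dims[axis].items()]
    if name in existing:
        raise CreationError(
            f"a scale named {name!r} is already attached to axis {axis}"
        )
    resizable = axis == 1 and bool(obj.attrs.get(_AUTO_EXPAND_ATTR, False))
    ds = _attach_scale(
        obj, raw, axis, name, name, unit, data, description, resizable=resizable
    )
    return DimensionScaleRecord(
        name=name, unit=unit, data=np.asarray(data), description=description,
        axis=axis, dataset=ds.name,
    )


def get_dimension_scales(ephys, axis=None) -> List[DimensionScaleRecord]:
    """All dimension scales of the primary dataset, optionally one axis only.

    Each record carries all five fields: data, unit, description, name, axis.
    """
    obj = ephys.obj if isinstance(ephys, ManagedObjectHandle) else ephys
    raw = obj["raw_data"]
    records = []
    axes = range(raw.ndim) if axis is None else [axis]
    for ax in axes:
        for scale_name, scale in raw.dims[ax].items():
            records.append(
                DimensionScaleRecord(
                    name=scale_name,
                    unit=_decode(scale.attrs.get("unit", "")),
                    data=scale[()],
                    description=_decode(scale.attrs.get("description", "")),
                    axis=ax,
                    dataset=scale.name,
                )
            )
    return records


def _decode(v):
    return v.decode("utf-8") if isinstance(v, bytes) else v


def read(ephys, selection=None):
    """Array read of the primary dataset (full array when no selection)."""
    obj = ephys.obj if isinstance(ephys, ManagedObjectHandle) else ephys
    raw = obj["raw_data"]
    if selection is None:
        return raw[()]
    if isinstance(selection, Selection):
        return selection.read(raw)
    return raw[selection]


def aux(ephys, key):
    """Key-based access to auxiliary data: ``sampling_rate``, ``unit``, or a
    dimension-scale dataset name."""
    obj = ephys.obj if isinstance(ephys, ManagedObjectHandle) else ephys
    if key == "sampling_rate":
        return float(obj["sampling_rate"][()])
    if key == "unit":
        return _decode(obj["raw_data"].attrs["unit"])
    raw = obj["raw_data"]
    for ax in range(raw.ndim):
        for scale_name, scale in raw.dims[ax].items():
            ds_name = scale.name.rsplit("/", 1)[-1]
            if key in (scale_name, ds_name):
                return scale[()]
    raise ObjectLookupError(f"unknown auxiliary key {key!r}")


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def _register(registry):
    registry.register(
        "BrainDataFile", _session_file_spec, populate=_populate_session,
        kind="file",
    )
    registry.register(
        "BrainDataCollection", _collection_spec, kind="group",
    )
    registry.register(
        "BrainDataEphys", _ephys_spec, populate=_populate_ephys,
        kind="group", handle_class=EphysGroup,
    )
    registry.register(
        "BrainDataEphysProcessed", _processed_spec, populate=_populate_processed,
        base="BrainDataEphys", kind="group", handle_class=ProcessedEphysGroup,
    )


_register(DEFAULT_REGISTRY)
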