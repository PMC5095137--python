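"""Relationship attributes.

A relationship attribute is a JSON-valued HDF5 attribute on a *source*
object declaring a typed structural/semantic link to a *target* object.  The
attribute name is the reserved prefix ``RELATIONSHIP_ATTR_`` plus the
user-chosen name (plus a reserved postfix when the attribute is one leg of an
index-map relationship).

Seven semantic types are supported.  Six of them imply a rule for mapping
selections from the source to the target:

* ``order`` / ``equivalent`` — identity on indices along the related axes
  (alphabetic ordinal positions for groups);
* ``indexes`` — the source stores indices into the target; mapping gathers
  the index values at the selected positions;
* ``shared_encoding`` / ``indexes_values`` — value matching: all target
  positions whose value equals any selected source value;
* ``shared_ascending_encoding`` — both sides sorted ascending; range
  selections map to all target positions within the [min, max] of the
  selected source values, point selections fall back to value matching.

The ``user`` type carries custom semantics and implies no mapping.

Mapped index-list results from value matching and from stacked (N-to-M)
index maps are deduplicated and ascending; plain scalar gathers through an
``indexes`` relationship preserve selection order (gather semantics).
"""

from __future__ import annotations

import json
import os
import warnings
from typing import List, Optional

import h5py
import numpy as np

from .errors import (
    NoImpliedMappingError,
    ObjectLookupError,
    RelationshipError,
    SelectionError,
)
from .selection import Selection
from .spec import (
    RELATIONSHIP_TYPES,
    RelationshipSpec,
    RelationshipTarget,
    validate_spec_document,
)

__all__ = [
    "RELATIONSHIP_PREFIX",
    "IMR_POSTFIXES",
    "IMR_LEGS",
    "RelationshipDescriptor",
    "RelationshipAttribute",
    "create_relationship_attribute",
    "list_relationship_attributes",
    "find_relationships",
    "map_selection",
    "select_through",
    "IndexMapRelationship",
    "IndexMapScan",
    "create_index_map_relationship",
    "get_index_map_relationships",
]

RELATIONSHIP_PREFIX = "RELATIONSHIP_ATTR_"

#: Reserved attribute-name postfixes of the index-map relationship legs.
IMR_POSTFIXES = {
    "SOURCE_TO_MAP": "_IMR_SOURCE_TO_MAP",
    "MAP_TO_SOURCE": "_IMR_MAP_TO_SOURCE",
    "MAP_TO_TARGET": "_IMR_MAP_TO_TARGET",
    "SOURCE_TO_TARGET": "_IMR_SOURCE_TO_TARGET",
}
IMR_LEGS = tuple(IMR_POSTFIXES)
_IMR_REQUIRED = ("SOURCE_TO_MAP", "MAP_TO_SOURCE", "MAP_TO_TARGET")

# The stored JSON value of a relationship attribute has the same shape as a
# relationship specification node.
RelationshipDescriptor = RelationshipSpec


def _obj_of(x):
    from .managed import ManagedObjectHandle  # local to avoid import cycle

    if isinstance(x, ManagedObjectHandle):
        return x.obj
    if isinstance(x, h5py.File):
        return x["/"]
    return x


class RelationshipAttribute:
    """Handle onto one stored relationship attribute."""

    def __init__(self, source, name: str, descriptor: RelationshipDescriptor):
        self.source = _obj_of(source)
        self.name = name
        self.descriptor = descriptor
        self._ext_file = None  # keeps an external target file open

    @property
    def attr_name(self) -> str:
        return RELATIONSHIP_PREFIX + self.name

    @property
    def relationship_type(self) -> str:
        return self.descriptor.relationship_type

    def resolve_target(self):
        """The target HDF5 object; raises :class:`ObjectLookupError` when the
        target is dangling."""
        loc = self.descriptor.target.location
        try:
            if isinstance(loc, dict):
                base = os.path.dirname(os.path.abspath(self.source.file.filename))
                if self._ext_file is None:
                    self._ext_file = h5py.File(
                        os.path.join(base, loc["file"]), "r"
                    )
                return self._ext_file[loc["path"]]
            return self.source.file[loc]
        except (KeyError, OSError) as exc:
            raise ObjectLookupError(
                f"relationship {self.name!r}: target {loc!r} cannot be resolved: "
                f"{exc}"
            ) from exc

    def map(self, selection) -> Selection:
        return map_selection(self, selection)

    def __getitem__(self, key) -> Selection:
        if not isinstance(key, tuple):
            key = (key,)
        return map_selection(self, Selection.axes(key))

    def __repr__(self):
        return (
            f"<RelationshipAttribute {self.name!r} "
            f"({self.relationship_type}) on {self.source.name!r}>"
        )


def _load_descriptor(obj, attr_name) -> RelationshipDescriptor:
    raw = obj.attrs[attr_name]
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8")
    return RelationshipDescriptor.from_dict(json.loads(raw))


def create_relationship_attribute(
    source,
    name: str,
    descriptor: RelationshipDescriptor,
    allow_dangling: bool = False,
) -> RelationshipAttribute:
    """Store a relationship attribute on ``source``.

    The descriptor must be meta-valid and its target resolvable (unless
    ``allow_dangling`` is set, in which case a warning is issued and
    verification later reports a warning finding).
    """
    obj = _obj_of(source)
    attr_name = RELATIONSHIP_PREFIX + name
    if attr_name in obj.attrs:
        raise RelationshipError(
            f"relationship attribute {name!r} already exists on {obj.name!r}"
        )
    if descriptor.relationship_type not in RELATIONSHIP_TYPES:
        raise RelationshipError(
            f"unknown relationship_type {descriptor.relationship_type!r}"
        )
    descriptor.attribute = name
    report = validate_spec_document(descriptor)
    errors = [f for f in report if f["severity"] == "error"]
    if errors:
        raise RelationshipError(
            f"invalid relationship descriptor: {errors[0]['message']}"
        )
    handle = RelationshipAttribute(obj, name, descriptor)
    try:
        handle.resolve_target()
    except ObjectLookupError:
        if not allow_dangling:
            raise
        warnings.warn(
            f"relationship {name!r} created with dangling target "
            f"{descriptor.target.location!r}"
        )
    obj.attrs[attr_name] = json.dumps(descriptor.to_dict())
    return handle


def list_relationship_attributes(source) -> List[RelationshipAttribute]:
    """All relationship attributes stored on ``source``, name-sorted."""
    obj = _obj_of(source)
    out = []
    for attr_name in sorted(obj.attrs):
        if attr_name.startswith(RELATIONSHIP_PREFIX):
            name = attr_name[len(RELATIONSHIP_PREFIX):]
            out.append(RelationshipAttribute(obj, name, _load_descriptor(obj, attr_name)))
    return out


def find_relationships(source, target) -> List[RelationshipAttribute]:
    """Relationship attributes on ``source`` whose resolved target is
    ``target`` (deterministic name-sorted order; empty list on no match)."""
    tgt = _obj_of(target)
    out = []
    for rel in list_relationship_attributes(source):
        try:
            resolved = rel.resolve_target()
        except ObjectLookupError:
            continue
        if resolved == tgt:
            out.append(rel)
    return out


# ---------------------------------------------------------------------------
# Selection mapping
# ---------------------------------------------------------------------------


def _coerce_selection(selection) -> Selection:
    if isinstance(selection, Selection):
        return selection
    if isinstance(selection, tuple):
        return Selection.axes(selection)
    return Selection.axes((selection,))


def _related_axes(axes_field, default_ndim):
    """Normalize a source_axes/target.axes field to a list of axis indices."""
    if axes_field is None:
        return list(range(default_ndim))
    if isinstance(axes_field, int):
        return [axes_field]
    if isinstance(axes_field, dict):
        return [axes_field[k] for k in sorted(axes_field)]
    return list(axes_field)


def _map_order(rel, sel: Selection) -> Selection:
    src = rel.source
    tgt = rel.resolve_target()
    if isinstance(src, h5py.Group):
        names = sorted(src.keys())
        tnames = sorted(tgt.keys()) if isinstance(tgt, h5py.Group) else None
        if sel.kind == "members":
            ordinals = []
            for n in sel.names:
                if n not in names:
                    raise SelectionError(f"{n!r} is not a member of {src.name!r}")
                ordinals.append(names.index(n))
        else:
            ordinals = [int(i) for i in sel.axis_indices(0, len(names))]
        if tnames is None:
            return Selection.from_indices(ordinals)
        try:
            return Selection.members([tnames[i] for i in ordinals])
        except IndexError:
            raise SelectionError(
                f"ordinal selection exceeds target group size {len(tnames)}"
            ) from None
    # datasets: identity on indices along the related axes
    if sel.kind == "axes":
        axes = _related_axes(rel.descriptor.source_axes, len(sel.selectors))
        for i, s in enumerate(sel.selectors):
            axis = axes[i] if i < len(axes) else i
            if axis >= src.ndim:
                raise SelectionError(
                    f"selection axis {axis} exceeds source rank {src.ndim}"
                )
            Selection._axis_indices(s, src.shape[axis])
    elif sel.kind == "points":
        sel.positions(src.shape)
    return sel


def _gather_indexes(rel, sel: Selection):
    """Apply an indexes relationship: read index values at the selected
    source positions and interpret them as positions in the target."""
    src = rel.source
    tgt = rel.resolve_target()
    if not isinstance(src, h5py.Dataset):
        raise SelectionError("indexes relationships require a dataset source")
    target_rank = 1 if isinstance(tgt, h5py.Group) else tgt.ndim
    props = rel.descriptor.properties or {}
    fill = props.get("fill", -1)
    spatial = _related_axes(
        rel.descriptor.source_axes,
        sel.ndim if sel.ndim is not None else src.ndim,
    )
    n_spatial = len(spatial)
    if spatial != list(range(n_spatial)):
        raise SelectionError(
            "indexes relationships require the related source axes to be the "
            "leading axes of the index dataset"
        )
    positions = sel.positions(src.shape[:n_spatial])

    scalar_entries = src.ndim == n_spatial
    gathered_scalars = []  # order-preserving gather (scalar entries, 1-D target)
    point_set = []  # multi-valued: dedup + ascending
    for pos in positions:
        vals = np.asarray(src[pos])
        if vals.ndim == 0:
            if target_rank != 1:
                raise SelectionError(
                    f"scalar index entries cannot address a rank-{target_rank} "
                    "target"
                )
            v = int(vals)
            if v == fill:
                continue
            gathered_scalars.append(v)
        elif target_rank == 1:
            for v in vals.reshape(-1):
                v = int(v)
                if v != fill:
                    point_set.append((v,))
        else:
            if vals.ndim == 1:
                if vals.shape[0] != target_rank:
                    raise SelectionError(
                        f"index entry of length {vals.shape[0]} cannot address "
                        f"a rank-{target_rank} target"
                    )
                cols = vals.reshape(target_rank, 1)
            elif vals.ndim == 2 and vals.shape[0] == target_rank:
                cols = vals
            else:
                raise SelectionError(
                    f"cannot interpret index entries of shape {vals.shape} for "
                    f"a rank-{target_rank} target"
                )
            for j in range(cols.shape[1]):
                pt = tuple(int(c) for c in cols[:, j])
                if any(c == fill for c in pt):
                    continue
                point_set.append(pt)
    if scalar_entries and target_rank == 1:
        return Selection.from_indices(gathered_scalars)
    return Selection.from_points(point_set)


def _value_match(rel, sel: Selection) -> Selection:
    src, tgt = rel.source, rel.resolve_target()
    svals = np.asarray(sel.read(src)).reshape(-1)
    tvals = np.asarray(tgt[()])
    if svals.size == 0:
        return Selection.from_indices([])
    if tvals.ndim == 1:
        hits = np.nonzero(np.isin(tvals, svals))[0]
        return Selection.from_indices([int(i) for i in hits])
    hits = np.argwhere(np.isin(tvals, svals))
    return Selection.from_points([tuple(int(c) for c in row) for row in hits])


def _range_match(rel, sel: Selection) -> Selection:
    src, tgt = rel.source, rel.resolve_target()
    svals = np.asarray(sel.read(src)).reshape(-1)
    if svals.size == 0:
        return Selection.from_indices([])
    lo, hi = svals.min(), svals.max()
    tvals = np.asarray(tgt[()]).reshape(-1)
    hits = np.nonzero((tvals >= lo) & (tvals <= hi))[0]
    return Selection.from_indices([int(i) for i in hits])


def _is_range_selection(sel: Selection) -> bool:
    return sel.kind == "axes" and all(isinstance(s, slice) for s in sel.selectors)


def map_selection(rel: RelationshipAttribute, selection) -> Selection:
    """Map a selection on the relationship's source to a selection on its
    target, per the rule implied by the relationship type.

    ``user`` relationships imply no mapping and raise
    :class:`NoImpliedMappingError`.  A value match with zero hits yields an
    empty selection, not an error.
    """
    sel = _coerce_selection(selection)
    rtype = rel.relationship_type
    if rtype == "user":
        raise NoImpliedMappingError(
            "user relationships do not imply a mapping between data elements"
        )
    if rtype in ("order", "equivalent"):
        return _map_order(rel, sel)
    if rtype == "indexes":
        return _gather_indexes(rel, sel)
    if rtype in ("shared_encoding", "indexes_values"):
        return _value_match(rel, sel)
    if rtype == "shared_ascending_encoding":
        if _is_range_selection(sel):
            return _range_match(rel, sel)
        return _value_match(rel, sel)
    raise RelationshipError(f"unknown relationship_type {rtype!r}")


def select_through(rel: RelationshipAttribute, selection):
    """Map the selection and read the corresponding values from the target."""
    mapped = map_selection(rel, selection)
    tgt = rel.resolve_target()
    if mapped.kind == "members":
        return [tgt[name] for name in mapped.names]
    return mapped.read(tgt)


# ---------------------------------------------------------------------------
# Index map relationships
# ---------------------------------------------------------------------------


class IndexMapRelationship:
    """Bundle of the 3-4 relationship attributes that realize an index-map
    chain: source array A, index map M, target array B."""

    def __init__(self, base_name: str, legs: dict):
        self.base_name = base_name
        self.legs = dict(legs)

    @property
    def source(self):
        return self.legs["SOURCE_TO_MAP"].source

    @property
    def index_map(self):
        return self.legs["MAP_TO_TARGET"].source

    @property
    def target(self):
        return self.legs["MAP_TO_TARGET"].resolve_target()

    def leg(self, name: str) -> RelationshipAttribute:
        key = name.upper()
        if key not in IMR_POSTFIXES:
            raise ObjectLookupError(f"unknown index-map leg {name!r}")
        if key == "SOURCE_TO_TARGET":
            # composed; the stored user leg (if any) carries no mapping
            raise ObjectLookupError(
                "SOURCE_TO_TARGET is computed by composition; use map()"
            )
        if key not in self.legs:
            raise ObjectLookupError(f"leg {name!r} is missing from this bundle")
        return self.legs[key]

    def map(self, leg: str, selection) -> Selection:
        return imr_map(self, leg, selection)

    def __getitem__(self, leg: str):
        return _ImrLegMapper(self, leg)

    def __repr__(self):
        return (
            f"<IndexMapRelationship {self.base_name!r} legs="
            f"{sorted(self.legs)}>"
        )


class _ImrLegMapper:
    """Sugar so that ``imr['MAP_TO_TARGET'][36, 70]`` maps a selection."""

    def __init__(self, imr, leg):
        self.imr = imr
        self.leg = leg

    def __getitem__(self, key):
        if not isinstance(key, tuple):
            key = (key,)
        return imr_map(self.imr, self.leg, Selection.axes(key))


def _canonical(sel: Selection) -> Selection:
    """Deduplicated, ascending form of an index-list selection."""
    if sel.kind == "points":
        return Selection.from_points(sel.point_list)
    if sel.kind == "axes" and len(sel.selectors) == 1:
        s = sel.selectors[0]
        if isinstance(s, tuple):
            return Selection.from_points([(i,) for i in s])
        if isinstance(s, int):
            return Selection.from_indices([s])
    return sel


def imr_map(imr: IndexMapRelationship, leg: str, selection) -> Selection:
    """Map a selection through one leg of an index-map relationship.

    ``SOURCE_TO_TARGET`` composes the order leg (A to M) with the indexes leg
    (M to B), so it is available even when the optional stored user leg was
    never created.  Results of index gathering are deduplicated and returned
    in ascending order; stacking-axis fill sentinels are dropped.
    """
    key = leg.upper()
    sel = _coerce_selection(selection)
    if key == "SOURCE_TO_TARGET":
        mid = map_selection(imr.leg("SOURCE_TO_MAP"), sel)
        return _canonical(map_selection(imr.leg("MAP_TO_TARGET"), mid))
    rel = imr.leg(key)
    out = map_selection(rel, sel)
    if key == "MAP_TO_TARGET":
        return _canonical(out)
    return out


def create_index_map_relationship(
    source,
    index_map,
    target,
    base_name: str,
    user_properties: Optional[dict] = None,
    fill: int = -1,
    description: str = "",
) -> IndexMapRelationship:
    """Create the full index-map relationship chain in one call.

    Creates an order relationship A to M, its inverse order M to A, and an
    indexes relationship M to B under ``base_name`` plus the reserved
    postfixes.  Iff ``user_properties`` is given, a fourth, user-type leg A
    to B is created.  Any leg failure rolls back all legs.
    """
    a, m, b = _obj_of(source), _obj_of(index_map), _obj_of(target)
    if not isinstance(m, h5py.Dataset) or not np.issubdtype(m.dtype, np.integer):
        raise RelationshipError("the index map must be an integer dataset")
    n_spatial = a.ndim if isinstance(a, h5py.Dataset) else 1
    spatial = list(range(n_spatial))
    target_rank = b.ndim if isinstance(b, h5py.Dataset) else 1
    extra = m.ndim - n_spatial
    if extra < 0:
        raise RelationshipError(
            f"index map rank {m.ndim} is smaller than the source spatial rank "
            f"{n_spatial}"
        )
    if target_rank > 1 and extra >= 1 and m.shape[n_spatial] != target_rank:
        raise RelationshipError(
            f"index axis has length {m.shape[n_spatial]} but the target has "
            f"rank {target_rank}"
        )

    props = {"fill": fill}
    if extra >= 1:
        props["index_axis"] = n_spatial if target_rank > 1 else None
        props["stack_axis"] = (
            n_spatial + 1 if target_rank > 1 and extra == 2
            else (n_spatial if target_rank == 1 else None)
        )

    legs_spec = [
        (
            a,
            "SOURCE_TO_MAP",
            RelationshipDescriptor(
                relationship_type="order",
                description=description
                or "Elements of the source are ordered as in the index map.",
                source_axes=spatial,
                target=RelationshipTarget(location=m.name, axes=spatial),
            ),
        ),
        (
            m,
            "MAP_TO_SOURCE",
            RelationshipDescriptor(
                relationship_type="order",
                description="Elements of the index map are ordered as in the "
                "source.",
                source_axes=spatial,
                target=RelationshipTarget(location=a.name, axes=spatial),
            ),
        ),
        (
            m,
            "MAP_TO_TARGET",
            RelationshipDescriptor(
                relationship_type="indexes",
                description="The index map stores indices into the target.",
                properties=props,
                source_axes=spatial,
                target=RelationshipTarget(
                    location=b.name, axes=list(range(target_rank))
                ),
            ),
        ),
    ]
    if user_properties is not None:
        legs_spec.append(
            (
                a,
                "SOURCE_TO_TARGET",
                RelationshipDescriptor(
                    relationship_type="user",
                    description="User-characterized relationship between "
                    "source and target.",
                    properties=dict(user_properties),
                    target=RelationshipTarget(location=b.name),
                ),
            )
        )

    created = []
    legs = {}
    try:
        for obj, leg, desc in legs_spec:
            name = base_name + IMR_POSTFIXES[leg]
            legs[leg] = create_relationship_attribute(obj, name, desc)
            created.append((obj, RELATIONSHIP_PREFIX + name))
    except Exception:
        for obj, attr_name in created:
            if attr_name in obj.attrs:
                del obj.attrs[attr_name]
        raise
    return IndexMapRelationship(base_name, legs)


class IndexMapScan:
    """Result of scanning for index-map relationship bundles."""

    def __init__(self, bundles, findings):
        self.bundles: List[IndexMapRelationship] = bundles
        self.findings: List[dict] = findings

    def __iter__(self):
        return iter(self.bundles)

    def __len__(self):
        return len(self.bundles)


def _iter_objects(root):
    """Root object plus (for groups) all resolvable descendants."""
    yield root
    if isinstance(root, h5py.Group):
        stack = [root]
        visited = set()
        while stack:
            g = stack.pop()
            key = (g.file.filename, g.name)
            if key in visited:
                continue
            visited.add(key)
            for name in sorted(g):
                try:
                    child = g[name]
                except KeyError:
                    continue
                yield child
                if isinstance(child, h5py.Group):
                    stack.append(child)


def get_index_map_relationships(container) -> IndexMapScan:
    """Locate index-map relationship bundles under ``container``.

    Co-named postfixed attributes are grouped into bundles by base name.
    Bundles missing a required leg are reported as findings, not returned.
    """
    root = _obj_of(container)
    by_base = {}
    for obj in _iter_objects(root):
        for attr_name in obj.attrs:
            if not attr_name.startswith(RELATIONSHIP_PREFIX):
                continue
            name = attr_name[len(RELATIONSHIP_PREFIX):]
            for leg, postfix in IMR_POSTFIXES.items():
                if name.endswith(postfix):
                    base = name[: -len(postfix)]
                    by_base.setdefault(base, {})[leg] = RelationshipAttribute(
                        obj, name, _load_descriptor(obj, attr_name)
                    )
                    break
    bundles, findings = [], []
    for base in sorted(by_base):
        legs = by_base[base]
        missing = [leg for leg in _IMR_REQUIRED if leg not in legs]
        if missing:
            findings.append(
                {
                    "base_name": base,
                    "rule": "incomplete-imr-bundle",
                    "missing_legs": missing,
                    "message": f"index-map bundle {base!r} is missing required "
                    f"legs {missing}",
                }
            )
        else:
            bundles.append(IndexMapRelationship(base, legs))
    return IndexMapScan(bundles, findings)
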