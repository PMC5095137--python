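"""Format specification documents.

A specification document is a hierarchical, JSON-serializable description of
an HDF5 file, group, or dataset and its required contents: attributes,
dimension scales, child datasets/groups, references to other managed types,
and relationship attributes.  Documents are built incrementally with the
``add_*`` methods (or :func:`attach_child_spec`), validated against the
meta-schema with :func:`validate_spec_document`, serialized with
:func:`spec_to_json` / :func:`spec_from_json`, and compiled recursively with
:func:`compile_recursive_spec`.

Conventions used throughout: axis indices are 0-based; ranges are half-open
``[start, stop)``; for every node exactly one of the exact name and the
prefix is non-null, and a prefix matches any child whose name starts with it.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Union

from .errors import (
    SpecCollisionError,
    SpecCycleError,
    SpecError,
    SpecKindError,
    SpecParseError,
    SpecResolutionError,
)

__all__ = [
    "RELATIONSHIP_TYPES",
    "AttributeSpec",
    "DimensionSpec",
    "RelationshipTarget",
    "RelationshipSpec",
    "DatasetSpec",
    "GroupSpec",
    "FileSpec",
    "ManagedRef",
    "FormatDocument",
    "attach_child_spec",
    "validate_spec_document",
    "spec_to_json",
    "spec_from_json",
    "spec_from_dict",
    "compile_recursive_spec",
    "compile_format_document",
]

#: The seven supported semantic relationship types.
RELATIONSHIP_TYPES = (
    "order",
    "equivalent",
    "indexes",
    "shared_encoding",
    "shared_ascending_encoding",
    "indexes_values",
    "user",
)


def _name_prefix_ok(name, prefix):
    """Exactly one of (name, prefix) must be a non-empty string."""
    return (name is None) != (prefix is None)


@dataclass
class AttributeSpec:
    """Specification of a single HDF5 attribute.

    ``value`` pins the attribute to a fixed literal: verification requires
    the stored attribute to equal it exactly.
    """

    attribute: Optional[str] = None
    prefix: Optional[str] = None
    value: Any = None
    optional: bool = False
    description: str = ""

    def key(self) -> str:
        return self.attribute if self.attribute is not None else self.prefix

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "prefix": self.prefix,
            "value": self.value,
            "optional": self.optional,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSpec":
        return cls(
            attribute=d.get("attribute"),
            prefix=d.get("prefix"),
            value=d.get("value"),
            optional=bool(d.get("optional", False)),
            description=d.get("description", ""),
        )


@dataclass
class DimensionSpec:
    """Specification of one dimension scale of a dataset."""

    name: str = ""
    unit: str = ""
    dataset: str = ""
    axis: int = 0
    description: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "unit": self.unit,
            "dataset": self.dataset,
            "axis": self.axis,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DimensionSpec":
        return cls(
            name=d.get("name", ""),
            unit=d.get("unit", ""),
            dataset=d.get("dataset", ""),
            axis=int(d.get("axis", 0)),
            description=d.get("description", ""),
        )


@dataclass
class RelationshipTarget:
    """Target half of a relationship: object location plus its related axes."""

    location: Any = None  # HDF5 path, or {"file": ..., "path": ...}
    axes: Any = None  # None | int | list of ints | {name: int}

    def to_dict(self) -> dict:
        return {"location": self.location, "axes": self.axes}

    @classmethod
    def from_dict(cls, d: dict) -> "RelationshipTarget":
        return cls(location=d.get("location"), axes=d.get("axes"))


@dataclass
class RelationshipSpec:
    """Specification of a relationship attribute on a source object."""

    attribute: str = ""
    relationship_type: str = "user"
    optional: bool = False
    description: str = ""
    properties: Dict[str, Any] = field(default_factory=dict)
    source_axes: Any = None  # None | int | list of ints | {name: int}
    target: RelationshipTarget = field(default_factory=RelationshipTarget)

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "relationship_type": self.relationship_type,
            "optional": self.optional,
            "description": self.description,
            "properties": dict(self.properties),
            "source_axes": copy.deepcopy(self.source_axes),
            "target": self.target.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelationshipSpec":
        return cls(
            attribute=d.get("attribute", ""),
            relationship_type=d.get("relationship_type", "user"),
            optional=bool(d.get("optional", False)),
            description=d.get("description", ""),
            properties=dict(d.get("properties") or {}),
            source_axes=copy.deepcopy(d.get("source_axes")),
            target=RelationshipTarget.from_dict(d.get("target") or {}),
        )


@dataclass
class DatasetSpec:
    """Specification of an HDF5 dataset with attributes, dimension scales,
    and relationship attributes."""

    dataset: Optional[str] = None
    prefix: Optional[str] = None
    optional: bool = False
    primary: bool = False
    description: str = ""
    attributes: List[AttributeSpec] = field(default_factory=list)
    dimensions: List[DimensionSpec] = field(default_factory=list)
    relationships: List[RelationshipSpec] = field(default_factory=list)
    managed_type: Optional[str] = None  # origin annotation set by the compiler

    def key(self) -> str:
        return self.dataset if self.dataset is not None else self.prefix

    # -- incremental builders -------------------------------------------------
    def add_attribute(self, spec: AttributeSpec) -> "DatasetSpec":
        if not isinstance(spec, AttributeSpec):
            raise SpecKindError(
                f"cannot attach {type(spec).__name__} as an attribute spec"
            )
        if any(a.key() == spec.key() for a in self.attributes):
            raise SpecCollisionError(f"duplicate attribute spec {spec.key()!r}")
        self.attributes.append(spec)
        return self

    def add_dimension(self, spec: DimensionSpec) -> "DatasetSpec":
        if not isinstance(spec, DimensionSpec):
            raise SpecKindError(
                f"cannot attach {type(spec).__name__} as a dimension spec"
            )
        if any((d.axis, d.name) == (spec.axis, spec.name) for d in self.dimensions):
            raise SpecCollisionError(
                f"duplicate dimension spec (axis={spec.axis}, name={spec.name!r})"
            )
        self.dimensions.append(spec)
        return self

    def add_relationship(self, spec: RelationshipSpec) -> "DatasetSpec":
        if not isinstance(spec, RelationshipSpec):
            raise SpecKindError(
                f"cannot attach {type(spec).__name__} as a relationship spec"
            )
        if any(r.attribute == spec.attribute for r in self.relationships):
            raise SpecCollisionError(f"duplicate relationship spec {spec.attribute!r}")
        self.relationships.append(spec)
        return self

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "dataset": self.dataset,
            "prefix": self.prefix,
            "optional": self.optional,
            "primary": self.primary,
            "description": self.description,
            "attributes": [a.to_dict() for a in self.attributes],
            "dimensions": [x.to_dict() for x in self.dimensions],
            "relationships": [r.to_dict() for r in self.relationships],
        }
        if self.managed_type is not None:
            d["managed_type"] = self.managed_type
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSpec":
        return cls(
            dataset=d.get("dataset"),
            prefix=d.get("prefix"),
            optional=bool(d.get("optional", False)),
            primary=bool(d.get("primary", False)),
            description=d.get("description", ""),
            attributes=[AttributeSpec.from_dict(a) for a in d.get("attributes", [])],
            dimensions=[DimensionSpec.from_dict(x) for x in d.get("dimensions", [])],
            relationships=[
                RelationshipSpec.from_dict(r) for r in d.get("relationships", [])
            ],
            managed_type=d.get("managed_type"),
        )


@dataclass
class ManagedRef:
    """Reference to another registered managed type contained in a group."""

    managed_type: str = ""
    optional: bool = False
    name: Optional[str] = None  # override of the referenced type's name
    prefix: Optional[str] = None  # override of the referenced type's prefix

    def to_dict(self) -> dict:
        return {
            "managed_type": self.managed_type,
            "optional": self.optional,
            "name": self.name,
            "prefix": self.prefix,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ManagedRef":
        return cls(
            managed_type=d.get("managed_type", ""),
            optional=bool(d.get("optional", False)),
            name=d.get("name"),
            prefix=d.get("prefix"),
        )


@dataclass
class GroupSpec:
    """Specification of an HDF5 group: keyed child datasets and groups,
    managed-type references, attributes, and relationship attributes."""

    group: Optional[str] = None
    prefix: Optional[str] = None
    optional: bool = False
    description: str = ""
    datasets: Dict[str, DatasetSpec] = field(default_factory=dict)
    groups: Dict[str, "GroupSpec"] = field(default_factory=dict)
    managed: List[Union[ManagedRef, "GroupSpec", DatasetSpec]] = field(
        default_factory=list
    )
    attributes: List[AttributeSpec] = field(default_factory=list)
    relationships: List[RelationshipSpec] = field(default_factory=list)
    managed_type: Optional[str] = None  # origin annotation set by the compiler

    def key(self) -> str:
        return self.group if self.group is not None else self.prefix

    # -- incremental builders -------------------------------------------------
    def add_dataset(self, spec: DatasetSpec, key: str) -> "GroupSpec":
        if not isinstance(spec, DatasetSpec):
            raise SpecKindError(
                f"cannot attach {type(spec).__name__} as a dataset spec"
            )
        if key in self.datasets:
            raise SpecCollisionError(f"duplicate dataset key {key!r}")
        self.datasets[key] = spec
        return self

    def add_group(self, spec: "GroupSpec", key: str) -> "GroupSpec":
        if not isinstance(spec, GroupSpec):
            raise SpecKindError(f"cannot attach {type(spec).__name__} as a group spec")
        if key in self.groups:
            raise SpecCollisionError(f"duplicate group key {key!r}")
        self.groups[key] = spec
        return self

    def add_managed(self, ref: ManagedRef) -> "GroupSpec":
        if not isinstance(ref, ManagedRef):
            raise SpecKindError(
                f"cannot attach {type(ref).__name__} as a managed reference"
            )
        if any(
            isinstance(m, ManagedRef) and m.managed_type == ref.managed_type
            for m in self.managed
        ):
            raise SpecCollisionError(
                f"duplicate managed reference {ref.managed_type!r}"
            )
        self.managed.append(ref)
        return self

    def add_attribute(self, spec: AttributeSpec) -> "GroupSpec":
        if not isinstance(spec, AttributeSpec):
            raise SpecKindError(
                f"cannot attach {type(spec).__name__} as an attribute spec"
            )
        if any(a.key() == spec.key() for a in self.attributes):
            raise SpecCollisionError(f"duplicate attribute spec {spec.key()!r}")
        self.attributes.append(spec)
        return self

    def add_relationship(self, spec: RelationshipSpec) -> "GroupSpec":
        if not isinstance(spec, RelationshipSpec):
            raise SpecKindError(
                f"cannot attach {type(spec).__name__} as a relationship spec"
            )
        if any(r.attribute == spec.attribute for r in self.relationships):
            raise SpecCollisionError(f"duplicate relationship spec {spec.attribute!r}")
        self.relationships.append(spec)
        return self

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "group": self.group,
            "prefix": self.prefix,
            "optional": self.optional,
            "description": self.description,
            "datasets": {k: v.to_dict() for k, v in self.datasets.items()},
            "groups": {k: v.to_dict() for k, v in self.groups.items()},
            "managed": [m.to_dict() for m in self.managed],
            "attributes": [a.to_dict() for a in self.attributes],
            "relationships": [r.to_dict() for r in self.relationships],
        }
        if self.managed_type is not None:
            d["managed_type"] = self.managed_type
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSpec":
        if cls is GroupSpec and d.get("group") == "/":
            return FileSpec.from_dict(d)
        out = cls(
            group=d.get("group"),
            prefix=d.get("prefix"),
            optional=bool(d.get("optional", False)),
            description=d.get("description", ""),
            datasets={
                k: DatasetSpec.from_dict(v) for k, v in d.get("datasets", {}).items()
            },
            groups={
                k: GroupSpec.from_dict(v) for k, v in d.get("groups", {}).items()
            },
            managed=[_managed_entry_from_dict(m) for m in d.get("managed", [])],
            attributes=[AttributeSpec.from_dict(a) for a in d.get("attributes", [])],
            relationships=[
                RelationshipSpec.from_dict(r) for r in d.get("relationships", [])
            ],
            managed_type=d.get("managed_type"),
        )
        return out


class FileSpec(GroupSpec):
    """A GroupSpec rooted at ``/`` describing a whole managed file."""

    def __init__(self, description: str = "", **kwargs):
        kwargs.pop("group", None)
        kwargs.pop("prefix", None)
        super().__init__(group="/", prefix=None, description=description, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "FileSpec":
        base = GroupSpec(
            group="/",
            datasets={
                k: DatasetSpec.from_dict(v) for k, v in d.get("datasets", {}).items()
            },
            groups={k: GroupSpec.from_dict(v) for k, v in d.get("groups", {}).items()},
            managed=[_managed_entry_from_dict(m) for m in d.get("managed", [])],
            attributes=[AttributeSpec.from_dict(a) for a in d.get("attributes", [])],
            relationships=[
                RelationshipSpec.from_dict(r) for r in d.get("relationships", [])
            ],
        )
        out = cls(description=d.get("description", ""))
        out.optional = bool(d.get("optional", False))
        out.datasets = base.datasets
        out.groups = base.groups
        out.managed = base.managed
        out.attributes = base.attributes
        out.relationships = base.relationships
        out.managed_type = d.get("managed_type")
        return out


def _managed_entry_from_dict(d: dict):
    """A managed entry is a ManagedRef, or an embedded (compiled) spec."""
    if "datasets" in d or "groups" in d:
        return GroupSpec.from_dict(d)
    if "primary" in d or "dimensions" in d:
        return DatasetSpec.from_dict(d)
    return ManagedRef.from_dict(d)


SpecDocument = Union[GroupSpec, DatasetSpec]

_CHILD_KINDS = (
    AttributeSpec,
    DimensionSpec,
    DatasetSpec,
    GroupSpec,
    ManagedRef,
    RelationshipSpec,
)


def attach_child_spec(parent, child, key: Optional[str] = None):
    """Attach ``child`` to ``parent``, dispatching on the child's kind.

    Attributes and relationships are legal on groups and datasets; dimension
    scales only on datasets; datasets, groups, and managed references only on
    groups.  Returns the (mutated) parent.
    """
    if not isinstance(child, _CHILD_KINDS):
        raise SpecKindError(f"{type(child).__name__} is not an attachable spec kind")
    if isinstance(parent, DatasetSpec):
        if isinstance(child, AttributeSpec):
            return parent.add_attribute(child)
        if isinstance(child, DimensionSpec):
            return parent.add_dimension(child)
        if isinstance(child, RelationshipSpec):
            return parent.add_relationship(child)
        raise SpecKindError(
            f"cannot attach {type(child).__name__} to a DatasetSpec"
        )
    if isinstance(parent, GroupSpec):
        if isinstance(child, AttributeSpec):
            return parent.add_attribute(child)
        if isinstance(child, RelationshipSpec):
            return parent.add_relationship(child)
        if isinstance(child, DatasetSpec):
            return parent.add_dataset(child, key if key is not None else child.key())
        if isinstance(child, GroupSpec):
            return parent.add_group(child, key if key is not None else child.key())
        if isinstance(child, ManagedRef):
            return parent.add_managed(child)
        raise SpecKindError(f"cannot attach {type(child).__name__} to a GroupSpec")
    raise SpecKindError(f"{type(parent).__name__} cannot hold child specifications")


# ---------------------------------------------------------------------------
# Meta-validation
# ---------------------------------------------------------------------------


def _axes_shape(axes):
    """Classify an axes description for shape-agreement checks."""
    if axes is None:
        return ("none",)
    if isinstance(axes, int):
        return ("single",)
    if isinstance(axes, (list, tuple)):
        return ("list", len(axes))
    if isinstance(axes, dict):
        return ("map", frozenset(axes.keys()))
    return ("invalid",)


def _validate_node(node, path, report):
    err = lambda msg: report.append(
        {"path": path, "severity": "error", "message": msg}
    )
    if isinstance(node, AttributeSpec):
        if not _name_prefix_ok(node.attribute, node.prefix):
            err("exactly one of {attribute, prefix} must be non-null")
    elif isinstance(node, DimensionSpec):
        if not isinstance(node.axis, int) or node.axis < 0:
            err("dimension axis must be a non-negative integer")
        if not node.dataset:
            err("dimension spec requires a scale dataset name")
    elif isinstance(node, RelationshipSpec):
        if not node.attribute:
            err("relationship spec requires a non-empty attribute name")
        if node.relationship_type not in RELATIONSHIP_TYPES:
            err(
                f"relationship_type {node.relationship_type!r} is not one of "
                f"{RELATIONSHIP_TYPES}"
            )
        s = _axes_shape(node.source_axes)
        t = _axes_shape(node.target.axes)
        if s == ("invalid",):
            err("source_axes must be null, an int, a list of ints, or a name map")
        if t == ("invalid",):
            err("target.axes must be null, an int, a list of ints, or a name map")
        if s[0] in ("list", "map") and t[0] in ("list", "map") and s != t:
            err("source_axes and target.axes must have matching length/keys")
    elif isinstance(node, ManagedRef):
        if not node.managed_type:
            err("managed reference requires a managed_type name")
        if node.name is not None and node.prefix is not None:
            err("managed reference may override name or prefix, not both")
    elif isinstance(node, DatasetSpec):
        if not _name_prefix_ok(node.dataset, node.prefix):
            err("exactly one of {dataset, prefix} must be non-null")
        seen = set()
        for i, a in enumerate(node.attributes):
            if a.key() in seen:
                err(f"duplicate attribute spec {a.key()!r}")
            seen.add(a.key())
            _validate_node(a, f"{path}/attributes[{i}]", report)
        seen = set()
        for i, dim in enumerate(node.dimensions):
            k = (dim.axis, dim.name)
            if k in seen:
                err(f"duplicate dimension spec (axis={dim.axis}, name={dim.name!r})")
            seen.add(k)
            _validate_node(dim, f"{path}/dimensions[{i}]", report)
        seen = set()
        for i, r in enumerate(node.relationships):
            if r.attribute in seen:
                err(f"duplicate relationship spec {r.attribute!r}")
            seen.add(r.attribute)
            _validate_node(r, f"{path}/relationships[{i}]", report)
    elif isinstance(node, GroupSpec):
        if not _name_prefix_ok(node.group, node.prefix):
            err("exactly one of {group, prefix} must be non-null")
        for k, v in node.datasets.items():
            if not isinstance(v, DatasetSpec):
                err(f"dataset entry {k!r} is not a DatasetSpec")
                continue
            _validate_node(v, f"{path}/datasets/{k}", report)
        for k, v in node.groups.items():
            if not isinstance(v, GroupSpec):
                err(f"group entry {k!r} is not a GroupSpec")
                continue
            _validate_node(v, f"{path}/groups/{k}", report)
        for i, m in enumerate(node.managed):
            _validate_node(m, f"{path}/managed[{i}]", report)
        seen = set()
        for i, a in enumerate(node.attributes):
            if a.key() in seen:
                err(f"duplicate attribute spec {a.key()!r}")
            seen.add(a.key())
            _validate_node(a, f"{path}/attributes[{i}]", report)
        seen = set()
        for i, r in enumerate(node.relationships):
            if r.attribute in seen:
                err(f"duplicate relationship spec {r.attribute!r}")
            seen.add(r.attribute)
            _validate_node(r, f"{path}/relationships[{i}]", report)
    else:
        raise SpecError(f"not a specification node: {type(node).__name__}")
    return report


def validate_spec_document(doc) -> List[dict]:
    """Validate a specification document against the meta-schema.

    Returns a report: a list of ``{path, severity, message}`` findings.  An
    empty report means the document conforms.  A malformed input (not a
    hierarchical document at all) raises :class:`SpecError` instead.
    """
    if isinstance(doc, dict):
        doc = spec_from_dict(doc)
    if not isinstance(doc, _CHILD_KINDS):
        raise SpecError(
            f"not a specification document: {type(doc).__name__}"
        )
    return _validate_node(doc, "", [])


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def spec_from_dict(d: dict):
    """Reconstruct a spec node from its dictionary form.

    Dispatch is on key presence: dimension specs carry ``axis``; relationship
    specs carry ``relationship_type``; managed references carry
    ``managed_type`` (without child collections); dataset specs carry
    ``primary``; everything else with ``group``/``datasets`` is a group.
    """
    if not isinstance(d, dict):
        raise SpecError(f"expected a dict, got {type(d).__name__}")
    if "relationship_type" in d:
        return RelationshipSpec.from_dict(d)
    if "axis" in d and "unit" in d:
        return DimensionSpec.from_dict(d)
    if "datasets" in d or "groups" in d or "group" in d:
        return GroupSpec.from_dict(d)
    if "primary" in d or "dimensions" in d or "dataset" in d:
        return DatasetSpec.from_dict(d)
    if "managed_type" in d:
        return ManagedRef.from_dict(d)
    if "attribute" in d or "value" in d:
        return AttributeSpec.from_dict(d)
    raise SpecError(f"unrecognizable specification dictionary with keys {sorted(d)}")


def spec_to_json(doc, pretty: bool = False) -> str:
    """Serialize a spec node to a JSON document (UTF-8 text).

    Key ordering is stable (insertion order of ``to_dict``); ``pretty``
    adds indentation only.
    """
    return json.dumps(doc.to_dict(), indent=2 if pretty else None)


def spec_from_json(text: str):
    """Parse a JSON document back into a spec node.

    Unparseable text raises :class:`SpecParseError` carrying the position.
    """
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SpecParseError(
            f"invalid JSON at line {exc.lineno} column {exc.colno}: {exc.msg}"
        ) from exc
    return spec_from_dict(d)


# ---------------------------------------------------------------------------
# Recursive compilation
# ---------------------------------------------------------------------------


def _compile_node(node, registry, stack, path):
    if isinstance(node, GroupSpec):
        out = copy.copy(node)
        out.datasets = {
            k: _compile_node(v, registry, stack, f"{path}/datasets/{k}")
            for k, v in node.datasets.items()
        }
        out.groups = {
            k: _compile_node(v, registry, stack, f"{path}/groups/{k}")
            for k, v in node.groups.items()
        }
        out.attributes = [copy.deepcopy(a) for a in node.attributes]
        out.relationships = [copy.deepcopy(r) for r in node.relationships]
        compiled_managed = []
        for i, ref in enumerate(node.managed):
            if isinstance(ref, ManagedRef):
                ref_path = f"{path}/managed[{i}]"
                if not registry.has(ref.managed_type):
                    raise SpecResolutionError(
                        f"unknown managed type {ref.managed_type!r} at {ref_path}",
                        ref_path=ref_path,
                    )
                embedded = compile_recursive_spec(
                    ref.managed_type, registry, _stack=stack, _path=ref_path
                )
                if ref.name is not None:
                    _set_own_name(embedded, name=ref.name)
                elif ref.prefix is not None:
                    _set_own_name(embedded, prefix=ref.prefix)
                embedded.optional = ref.optional
                compiled_managed.append(embedded)
            else:
                compiled_managed.append(copy.deepcopy(ref))
        out.managed = compiled_managed
        return out
    if isinstance(node, DatasetSpec):
        return copy.deepcopy(node)
    return copy.deepcopy(node)


def _set_own_name(spec, name=None, prefix=None):
    if isinstance(spec, GroupSpec):
        spec.group, spec.prefix = name, prefix
    else:
        spec.dataset, spec.prefix = name, prefix


def compile_recursive_spec(type_name: str, registry, _stack=None, _path=""):
    """Compile the complete specification of a managed type.

    Every managed reference in the result is replaced by the referenced
    type's own recursively compiled specification, annotated with its origin
    type name.  Cyclic references raise :class:`SpecCycleError` listing the
    cycle; unknown types raise :class:`SpecResolutionError` naming the
    reference path.
    """
    stack = list(_stack or [])
    if type_name in stack:
        cycle = stack[stack.index(type_name):] + [type_name]
        raise SpecCycleError(
            f"cyclic managed-type reference: {' -> '.join(cycle)}", cycle=cycle
        )
    if not registry.has(type_name):
        raise SpecResolutionError(
            f"unknown managed type {type_name!r}", ref_path=_path or type_name
        )
    basic = registry.spec(type_name)
    compiled = _compile_node(basic, registry, stack + [type_name], _path or type_name)
    compiled.managed_type = type_name
    return compiled


# ---------------------------------------------------------------------------
# Format documents
# ---------------------------------------------------------------------------


@dataclass
class FormatDocument:
    """Complete format document: one basic spec per registered managed type."""

    format_name: str = "managedh5"
    version: str = "1.0.0"
    types: Dict[str, SpecDocument] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "format": self.format_name,
            "version": self.version,
            "types": {k: v.to_dict() for k, v in self.types.items()},
        }

    def to_json(self, pretty: bool = False) -> str:
        return json.dumps(self.to_dict(), indent=2 if pretty else None)

    @classmethod
    def from_dict(cls, d: dict) -> "FormatDocument":
        return cls(
            format_name=d.get("format", "managedh5"),
            version=d.get("version", "1.0.0"),
            types={k: spec_from_dict(v) for k, v in d.get("types", {}).items()},
        )

    @classmethod
    def from_json(cls, text: str) -> "FormatDocument":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SpecParseError(
                f"invalid JSON at line {exc.lineno} column {exc.colno}: {exc.msg}"
            ) from exc
        return cls.from_dict(d)

    def unresolved_refs(self) -> List[str]:
        """Managed references that do not resolve to a member of the document."""
        missing = []

        def walk(node):
            if isinstance(node, GroupSpec):
                for m in node.managed:
                    if isinstance(m, ManagedRef) and m.managed_type not in self.types:
                        missing.append(m.managed_type)
                for v in node.datasets.values():
                    walk(v)
                for v in node.groups.values():
                    walk(v)

        for spec in self.types.values():
            walk(spec)
        return missing


def compile_format_document(
    registry, format_name: str = "managedh5", version: str = "1.0.0"
) -> FormatDocument:
    """Compile the non-recursive format document from a managed-type registry.

    The document contains one entry per registered type, each entry being the
    type's basic (non-inlined) specification.  Per-type validation failures
    are aggregated into a :class:`SpecValidationError`-free report accessible
    on the returned document via ``validate_spec_document`` per member.
    """
    doc = FormatDocument(format_name=format_name, version=version)
    for name in registry.names():
        doc.types[name] = registry.spec(name)
    return doc
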