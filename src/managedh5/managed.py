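"""Managed HDF5 objects.

A managed object is an HDF5 file, group, or dataset carrying four reserved
descriptor attributes: its managed type, a human-readable description, the
JSON text of its basic format specification, and an optional unique object
identifier.  This module creates, wraps, discovers, and verifies managed
objects and supports modular (external-file) and multi-file storage.
"""

from __future__ import annotations

import json
import os
import re
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import h5py

from .errors import (
    CreationError,
    ObjectLookupError,
    VerificationError,
)
from .registry import DEFAULT_REGISTRY, ManagedTypeRegistry
from .spec import (
    AttributeSpec,
    DatasetSpec,
    FileSpec,
    GroupSpec,
    ManagedRef,
    spec_from_json,
    spec_to_json,
)

__all__ = [
    "MANAGED_TYPE_ATTR",
    "MANAGED_DESCRIPTION_ATTR",
    "MANAGED_SPEC_ATTR",
    "MANAGED_OBJECT_ID_ATTR",
    "Finding",
    "ComplianceReport",
    "ManagedObjectHandle",
    "create_managed_object",
    "create_managed_file",
    "wrap_managed_object",
    "verify_compliance",
    "find_managed_objects",
    "create_external_managed_object",
    "create_multifile_container",
    "add_entry",
]

# Reserved descriptor attribute names.
MANAGED_TYPE_ATTR = "MANAGED_TYPE"
MANAGED_DESCRIPTION_ATTR = "MANAGED_DESCRIPTION"
MANAGED_SPEC_ATTR = "MANAGED_SPEC"
MANAGED_OBJECT_ID_ATTR = "MANAGED_OBJECT_ID"

# Imported late to avoid a cycle with relationships.py
_REL_PREFIX = "RELATIONSHIP_ATTR_"


@dataclass
class Finding:
    path: str
    rule: str
    severity: str  # "error" | "warning"
    message: str

    def to_obj(self):
        return {
            "path": self.path,
            "rule": self.rule,
            "severity": self.severity,
            "message": self.message,
        }


@dataclass
class ComplianceReport:
    """Result of verifying an object against its format specification."""

    findings: List[Finding] = field(default_factory=list)
    spec_version: Optional[str] = None

    @property
    def compliant(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> List[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def add(self, path, rule, severity, message):
        self.findings.append(Finding(path, rule, severity, message))

    def to_obj(self):
        return {
            "compliant": self.compliant,
            "spec_version": self.spec_version,
            "findings": [f.to_obj() for f in self.findings],
        }

    def to_json(self, pretty=False):
        return json.dumps(self.to_obj(), indent=2 if pretty else None)

    def __str__(self):
        lines = [f"compliant: {self.compliant}"]
        for f in self.findings:
            lines.append(f"  [{f.severity}] {f.path}: ({f.rule}) {f.message}")
        return "\n".join(lines)


def _as_group(parent):
    """Resolve a parent argument (handle, File, or Group) to an h5py group."""
    if isinstance(parent, ManagedObjectHandle):
        return parent.obj
    if isinstance(parent, h5py.File):
        return parent["/"]
    if isinstance(parent, (h5py.Group, h5py.Dataset)):
        return parent
    raise TypeError(f"cannot interpret {type(parent).__name__} as an HDF5 location")


def _attr_str(obj, name):
    v = obj.attrs.get(name)
    if isinstance(v, bytes):
        v = v.decode("utf-8")
    return v


class ManagedObjectHandle:
    """Typed view of an HDF5 object carrying the managed descriptors.

    Unmanaged objects (missing the managed-type attribute) yield a generic
    handle with ``unmanaged`` set; only generic access is then allowed.
    """

    def __init__(self, obj, path=None, registry: ManagedTypeRegistry = None):
        self.obj = obj
        self.path = path if path is not None else obj.name
        self.registry = registry if registry is not None else DEFAULT_REGISTRY
        self.warnings: List[str] = []

    # -- descriptors ----------------------------------------------------------
    @property
    def managed_type(self) -> Optional[str]:
        return _attr_str(self.obj, MANAGED_TYPE_ATTR)

    @property
    def description(self) -> str:
        return _attr_str(self.obj, MANAGED_DESCRIPTION_ATTR) or ""

    @property
    def object_id(self) -> Optional[str]:
        return _attr_str(self.obj, MANAGED_OBJECT_ID_ATTR)

    @property
    def stored_spec(self):
        text = _attr_str(self.obj, MANAGED_SPEC_ATTR)
        return spec_from_json(text) if text else None

    @property
    def unmanaged(self) -> bool:
        return self.managed_type is None

    @property
    def kind(self) -> str:
        if isinstance(self.obj, h5py.Dataset):
            return "dataset"
        return "file" if self.obj.name == "/" else "group"

    @property
    def file(self):
        return self.obj.file

    # -- convenience ----------------------------------------------------------
    def __getitem__(self, key):
        return self.obj[key]

    def __contains__(self, key):
        return key in self.obj

    @property
    def attrs(self):
        return self.obj.attrs

    def verify(self) -> "ComplianceReport":
        return verify_compliance(self, registry=self.registry)

    def close(self):
        self.obj.file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False

    def __repr__(self):
        t = self.managed_type or "<unmanaged>"
        return f"<{type(self).__name__} {t} at {self.path!r}>"


# ---------------------------------------------------------------------------
# Creation
# ---------------------------------------------------------------------------


def _write_descriptors(obj, type_name, description, spec, object_id=None):
    obj.attrs[MANAGED_TYPE_ATTR] = type_name
    obj.attrs[MANAGED_DESCRIPTION_ATTR] = description
    obj.attrs[MANAGED_SPEC_ATTR] = spec_to_json(spec)
    if object_id is not None:
        obj.attrs[MANAGED_OBJECT_ID_ATTR] = object_id


def _resolve_name(spec, name):
    exact = spec.group if isinstance(spec, GroupSpec) else spec.dataset
    prefix = spec.prefix
    if exact is not None and exact != "/":
        if name is not None and name != exact:
            raise CreationError(
                f"type requires the exact name {exact!r}, got {name!r}"
            )
        return exact
    if prefix is not None:
        if name is None:
            raise CreationError(
                f"a name is required for prefix-named type (prefix {prefix!r})"
            )
        return name if name.startswith(prefix) else prefix + name
    if name is None:
        raise CreationError("a name is required")
    return name


def create_managed_object(
    parent,
    type_name: str,
    name: Optional[str] = None,
    payload: Optional[dict] = None,
    description: Optional[str] = None,
    object_id: Optional[str] = None,
    registry: ManagedTypeRegistry = None,
) -> ManagedObjectHandle:
    """Create a new managed object under ``parent``.

    The type's populate procedure receives the payload and must create every
    required child; the object is verified immediately and any failure rolls
    back by deleting the partially created object, so no invalid object
    remains.
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    group = _as_group(parent)
    entry = registry.get(type_name)
    if entry.kind == "file":
        raise CreationError(
            f"{type_name!r} is a file type; use create_managed_file"
        )
    spec = registry.spec(type_name)
    full_name = _resolve_name(spec, name)
    if full_name in group:
        raise CreationError(
            f"an object named {full_name!r} already exists in {group.name!r}"
        )
    obj = group.create_group(full_name)
    try:
        _write_descriptors(
            obj,
            type_name,
            description if description is not None else spec.description,
            spec,
            object_id,
        )
        if entry.populate is not None:
            entry.populate(obj, **(payload or {}))
        report = verify_compliance(obj, registry=registry)
        if not report.compliant:
            raise CreationError(
                f"populate left {type_name!r} non-compliant:\n{report}"
            )
    except Exception:
        del group[full_name]
        raise
    return wrap_managed_object(group.file, _join(group.name, full_name), registry)


def create_managed_file(
    path: str,
    type_name: str,
    payload: Optional[dict] = None,
    description: Optional[str] = None,
    object_id: Optional[str] = None,
    overwrite: bool = False,
    registry: ManagedTypeRegistry = None,
) -> ManagedObjectHandle:
    """Create a new managed file of a file-kind managed type."""
    registry = registry if registry is not None else DEFAULT_REGISTRY
    entry = registry.get(type_name)
    if entry.kind != "file":
        raise CreationError(f"{type_name!r} is not a file type")
    spec = registry.spec(type_name)
    mode = "w" if overwrite else "w-"
    try:
        f = h5py.File(path, mode)
    except (OSError, ValueError) as exc:
        raise CreationError(f"cannot create file {path!r}: {exc}") from exc
    try:
        root = f["/"]
        _write_descriptors(
            root,
            type_name,
            description if description is not None else spec.description,
            spec,
            object_id,
        )
        if entry.populate is not None:
            entry.populate(root, **(payload or {}))
        report = verify_compliance(root, registry=registry)
        if not report.compliant:
            raise CreationError(
                f"populate left {type_name!r} non-compliant:\n{report}"
            )
    except Exception:
        f.close()
        os.unlink(path)
        raise
    return wrap_managed_object(f, "/", registry)


def _join(base, name):
    return (base.rstrip("/") + "/" + name) if base != "/" else "/" + name


def wrap_managed_object(
    file, path: str = "/", registry: ManagedTypeRegistry = None
) -> ManagedObjectHandle:
    """Wrap a stored HDF5 object in a handle dispatched on its managed type.

    Unmanaged objects yield a generic handle flagged ``unmanaged``; objects
    whose stored type is not registered yield a generic handle and record a
    warning.
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    if isinstance(file, ManagedObjectHandle):
        file = file.obj
    root = file["/"] if isinstance(file, h5py.File) else file
    try:
        obj = root[path] if path not in ("/", "") else (
            root.file["/"] if isinstance(root, h5py.Group) else root
        )
    except KeyError as exc:
        raise ObjectLookupError(f"no object at {path!r}: {exc}") from exc
    handle = ManagedObjectHandle(obj, path=path, registry=registry)
    mtype = handle.managed_type
    if mtype is None:
        return handle
    if not registry.has(mtype):
        msg = f"object at {path!r} has unregistered managed type {mtype!r}"
        warnings.warn(msg)
        handle.warnings.append(msg)
        return handle
    cls = registry.handle_class_for(mtype)
    if cls is not None and cls is not ManagedObjectHandle:
        handle = cls(obj, path=path, registry=registry)
    return handle


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


def _children(group):
    """Yield (name, link, child-or-None) for each member; child is None for
    broken links."""
    for name in group:
        try:
            link = group.get(name, getlink=True)
        except KeyError:
            link = None
        try:
            child = group[name]
        except KeyError:
            child = None
        yield name, link, child


def _match_children(group, exact, prefix):
    """Members matching an exact name or a prefix; broken links included with
    child None."""
    out = []
    for name, link, child in _children(group):
        if exact is not None and name == exact:
            out.append((name, link, child))
        elif prefix is not None and name.startswith(prefix):
            out.append((name, link, child))
    return out


def _check_attributes(obj, attr_specs, path, report):
    for aspec in attr_specs:
        if aspec.attribute is not None:
            present = aspec.attribute in obj.attrs
            if not present:
                if not aspec.optional:
                    report.add(
                        path,
                        "required-attribute",
                        "error",
                        f"missing required attribute {aspec.attribute!r}",
                    )
                continue
            if aspec.value is not None:
                stored = _attr_str(obj, aspec.attribute)
                if stored != aspec.value:
                    report.add(
                        path,
                        "fixed-attribute-value",
                        "error",
                        f"attribute {aspec.attribute!r} must equal "
                        f"{aspec.value!r}, found {stored!r}",
                    )
        else:
            matches = [k for k in obj.attrs if k.startswith(aspec.prefix)]
            if not matches and not aspec.optional:
                report.add(
                    path,
                    "required-attribute",
                    "error",
                    f"no attribute with prefix {aspec.prefix!r}",
                )
            if aspec.value is not None:
                for k in matches:
                    if _attr_str(obj, k) != aspec.value:
                        report.add(
                            path,
                            "fixed-attribute-value",
                            "error",
                            f"attribute {k!r} must equal {aspec.value!r}",
                        )


def _check_relationships(obj, rel_specs, path, report):
    for rspec in rel_specs:
        attr_name = _REL_PREFIX + rspec.attribute
        if attr_name not in obj.attrs and not rspec.optional:
            report.add(
                path,
                "required-relationship",
                "error",
                f"missing relationship attribute {rspec.attribute!r}",
            )


def _verify_dataset(dset, dspec, path, report):
    if not isinstance(dset, h5py.Dataset):
        report.add(path, "object-kind", "error", "expected a dataset")
        return
    _check_attributes(dset, dspec.attributes, path, report)
    _check_relationships(dset, dspec.relationships, path, report)
    for dim in dspec.dimensions:
        if dim.axis >= dset.ndim:
            report.add(
                path,
                "dimension-axis",
                "error",
                f"dimension scale {dim.name!r} declared on axis {dim.axis} but "
                f"dataset rank is {dset.ndim}",
            )
            continue
        parent = dset.parent
        if dim.dataset not in parent:
            report.add(
                path,
                "dimension-scale",
                "error",
                f"scale dataset {dim.dataset!r} for axis {dim.axis} is missing",
            )
            continue
        scale = parent[dim.dataset]
        if scale.shape[0] != dset.shape[dim.axis]:
            report.add(
                path,
                "dimension-scale-length",
                "error",
                f"scale {dim.dataset!r} has length {scale.shape[0]} but axis "
                f"{dim.axis} has extent {dset.shape[dim.axis]}",
            )
        attached = any(s == scale for _, s in dset.dims[dim.axis].items())
        if not attached:
            report.add(
                path,
                "dimension-scale-attachment",
                "error",
                f"scale {dim.dataset!r} is not attached to axis {dim.axis}",
            )


def _verify_group(obj, gspec, path, report, registry, wrap_path):
    if not isinstance(obj, h5py.Group):
        report.add(path, "object-kind", "error", "expected a group")
        return
    _check_attributes(obj, gspec.attributes, path, report)
    _check_relationships(obj, gspec.relationships, path, report)

    for key, dspec in gspec.datasets.items():
        matches = _match_children(obj, dspec.dataset, dspec.prefix)
        if not matches and not dspec.optional:
            report.add(
                _join(path, dspec.dataset or dspec.prefix + "*"),
                "required-dataset",
                "error",
                f"missing required dataset {key!r}",
            )
        for name, link, child in matches:
            cpath = _join(path, name)
            if child is None:
                report.add(
                    cpath,
                    "broken-link",
                    "error",
                    f"link {name!r} cannot be resolved"
                    + (
                        f" (external file {link.filename!r})"
                        if isinstance(link, h5py.ExternalLink)
                        else ""
                    ),
                )
                continue
            _verify_dataset(child, dspec, cpath, report)

    for key, sub in gspec.groups.items():
        matches = _match_children(obj, sub.group, sub.prefix)
        if not matches and not sub.optional:
            report.add(
                _join(path, sub.group or sub.prefix + "*"),
                "required-group",
                "error",
                f"missing required group {key!r}",
            )
        for name, link, child in matches:
            cpath = _join(path, name)
            if child is None:
                report.add(cpath, "broken-link", "error",
                           f"link {name!r} cannot be resolved")
                continue
            _verify_group(child, sub, cpath, report, registry, _join(wrap_path, name))

    # broken links anywhere in a verified group are flagged
    for name, link, child in _children(obj):
        if child is None and isinstance(link, h5py.ExternalLink):
            cpath = _join(path, name)
            if not any(f.path == cpath and f.rule == "broken-link"
                       for f in report.findings):
                report.add(
                    cpath,
                    "broken-link",
                    "error",
                    f"external link {name!r} -> {link.filename!r} is dangling",
                )

    for ref in gspec.managed:
        if isinstance(ref, ManagedRef):
            found = []
            for name, link, child in _children(obj):
                if child is None:
                    continue
                ctype = _attr_str(child, MANAGED_TYPE_ATTR)
                if ctype is None:
                    continue
                if registry.has(ctype) and registry.is_subtype(ctype, ref.managed_type):
                    found.append((name, child, ctype))
            if not found and not ref.optional:
                report.add(
                    path,
                    "required-managed",
                    "error",
                    f"missing required managed object of type {ref.managed_type!r}",
                )
            for name, child, ctype in found:
                cpath = _join(path, name)
                # external managed children live in a container file; verify
                # against their own (stored) type
                sub_spec = registry.spec(ctype)
                if isinstance(sub_spec, GroupSpec):
                    _verify_group(child, sub_spec, cpath, report, registry,
                                  _join(wrap_path, name))
                else:
                    _verify_dataset(child, sub_spec, cpath, report)
                if sub_spec.prefix is not None and not name.startswith(
                    sub_spec.prefix
                ):
                    report.add(
                        cpath,
                        "name-prefix",
                        "error",
                        f"managed object of type {ctype!r} must have prefix "
                        f"{sub_spec.prefix!r}",
                    )
        else:
            # embedded (compiled) spec: behave like a plain child spec
            if isinstance(ref, GroupSpec):
                matches = _match_children(obj, ref.group, ref.prefix)
                if not matches and not ref.optional:
                    report.add(path, "required-managed", "error",
                               f"missing required managed member {ref.key()!r}")
                for name, link, child in matches:
                    _verify_group(child, ref, _join(path, name), report,
                                  registry, _join(wrap_path, name))
            elif isinstance(ref, DatasetSpec):
                matches = _match_children(obj, ref.dataset, ref.prefix)
                if not matches and not ref.optional:
                    report.add(path, "required-managed", "error",
                               f"missing required managed member {ref.key()!r}")
                for name, link, child in matches:
                    _verify_dataset(child, ref, _join(path, name), report)


def verify_compliance(
    target,
    spec=None,
    registry: ManagedTypeRegistry = None,
    spec_version: str = "1.0.0",
) -> ComplianceReport:
    """Verify format compliance of a managed object.

    ``target`` is a handle, an h5py object, or a ``(file, path)`` pair.  The
    spec defaults to the registered spec for the object's stored managed
    type, falling back to the spec stored with the object.  Verification
    follows minimal-specification semantics: everything specified must
    conform, extra objects never produce errors.

    Raises :class:`VerificationError` when no spec can be resolved at all
    (distinct from a non-compliant result).
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    if isinstance(target, tuple):
        file, path = target
        target = wrap_managed_object(file, path, registry)
    if isinstance(target, (h5py.Group, h5py.Dataset, h5py.File)):
        obj = target["/"] if isinstance(target, h5py.File) else target
        handle = ManagedObjectHandle(obj, registry=registry)
    else:
        handle = target
        obj = handle.obj

    if spec is None:
        mtype = _attr_str(obj, MANAGED_TYPE_ATTR)
        if mtype is not None and registry.has(mtype):
            spec = registry.spec(mtype)
        else:
            text = _attr_str(obj, MANAGED_SPEC_ATTR)
            if text:
                spec = spec_from_json(text)
    if spec is None:
        raise VerificationError(
            f"no resolvable specification for object at {obj.name!r}"
        )

    report = ComplianceReport(spec_version=spec_version)
    path = obj.name if obj.name else "/"
    if isinstance(spec, GroupSpec):
        _verify_group(obj, spec, path, report, registry, path)
    elif isinstance(spec, DatasetSpec):
        _verify_dataset(obj, spec, path, report)
    elif isinstance(spec, AttributeSpec):
        raise VerificationError("cannot verify an object against an attribute spec")
    else:
        raise VerificationError(f"unsupported spec kind {type(spec).__name__}")
    return report


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def find_managed_objects(
    container,
    type_name: Optional[str] = None,
    recursive: bool = True,
    exact: bool = False,
    registry: ManagedTypeRegistry = None,
) -> List[ManagedObjectHandle]:
    """All managed objects under ``container``, sorted by path.

    The type filter matches the type itself and, unless ``exact`` is set,
    any derived type.  External links are followed; broken links are skipped.
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    if isinstance(container, ManagedObjectHandle):
        root = container.obj
        base = container.path
    elif isinstance(container, h5py.File):
        root = container["/"]
        base = "/"
    else:
        root = container
        base = root.name or "/"

    results = []
    visited = set()

    def visit(group, path):
        key = (group.file.filename, group.name)
        if key in visited:
            return
        visited.add(key)
        for name in sorted(group):
            try:
                child = group[name]
            except KeyError:
                continue  # broken link
            cpath = _join(path, name)
            mtype = _attr_str(child, MANAGED_TYPE_ATTR)
            if mtype is not None:
                if type_name is None:
                    results.append(cpath)
                elif exact:
                    if mtype == type_name:
                        results.append(cpath)
                elif registry.has(mtype) and registry.is_subtype(mtype, type_name):
                    results.append(cpath)
            if recursive and isinstance(child, h5py.Group):
                visit(child, cpath)
            elif not recursive and isinstance(child, h5py.Group):
                pass

    if isinstance(root, h5py.Group):
        if recursive:
            visit(root, base)
        else:
            for name in sorted(root):
                try:
                    child = root[name]
                except KeyError:
                    continue
                mtype = _attr_str(child, MANAGED_TYPE_ATTR)
                if mtype is None:
                    continue
                if type_name is None or (
                    (mtype == type_name)
                    if exact
                    else (registry.has(mtype) and registry.is_subtype(mtype, type_name))
                ):
                    results.append(_join(base, name))
    results.sort()
    return [wrap_managed_object(root.file, p, registry) for p in results]


# ---------------------------------------------------------------------------
# External and multi-file storage
# ---------------------------------------------------------------------------


def _container_file_spec():
    return FileSpec(
        description="Generic file storage container for one managed object."
    )


def _multifile_spec():
    spec = FileSpec(description="Managed container grouping related files.")
    spec.add_group(
        GroupSpec(
            group=None,
            prefix="entry_",
            optional=True,
            description="External link to the root group of a member file.",
        ),
        "entry",
    )
    return spec


def create_external_managed_object(
    parent,
    type_name: str,
    external_path: str,
    name: str,
    payload: Optional[dict] = None,
    description: Optional[str] = None,
    registry: ManagedTypeRegistry = None,
) -> ManagedObjectHandle:
    """Create a managed object stored in its own external HDF5 file.

    The external file is a generic managed container holding the object; the
    parent gains an external link under ``name``, so wrap/verify/find behave
    identically to internal storage.
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    group = _as_group(parent)
    spec = registry.spec(type_name)
    full_name = _resolve_name(spec, name)
    if full_name in group:
        raise CreationError(
            f"an object named {full_name!r} already exists in {group.name!r}"
        )
    ext = h5py.File(external_path, "w-")
    try:
        _write_descriptors(
            ext["/"],
            "ManagedObjectContainer",
            "Container for externally stored managed object "
            f"{full_name!r} of type {type_name!r}.",
            _container_file_spec(),
        )
        create_managed_object(
            ext["/"],
            type_name,
            name=full_name,
            payload=payload,
            description=description,
            registry=registry,
        )
    except Exception:
        ext.close()
        os.unlink(external_path)
        raise
    ext.close()
    parent_dir = os.path.dirname(os.path.abspath(group.file.filename))
    rel = os.path.relpath(os.path.abspath(external_path), parent_dir)
    group[full_name] = h5py.ExternalLink(rel, "/" + full_name)
    return wrap_managed_object(group.file, _join(group.name, full_name), registry)


def create_multifile_container(
    path: str, overwrite: bool = False, registry: ManagedTypeRegistry = None
) -> ManagedObjectHandle:
    """Create an empty managed multi-file container."""
    registry = registry if registry is not None else DEFAULT_REGISTRY
    return create_managed_file(
        path, "BrainDataMultiFile", overwrite=overwrite, registry=registry
    )


_ENTRY_RE = re.compile(r"^entry_(\d+)$")


def add_entry(container, member_file: str, registry: ManagedTypeRegistry = None) -> str:
    """Add a managed member file to a multi-file container.

    Entries are named ``entry_0``, ``entry_1``, ... in dense, 0-based
    insertion order; each is an external link to the member file's root.
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    root = _as_group(container)
    with h5py.File(member_file, "r") as member:
        if MANAGED_TYPE_ATTR not in member["/"].attrs:
            raise CreationError(
                f"{member_file!r} is not a managed file (missing managed type)"
            )
    nums = [
        int(m.group(1))
        for m in (_ENTRY_RE.match(k) for k in root)
        if m is not None
    ]
    entry = f"entry_{len(nums)}"
    parent_dir = os.path.dirname(os.path.abspath(root.file.filename))
    rel = os.path.relpath(os.path.abspath(member_file), parent_dir)
    root[entry] = h5py.ExternalLink(rel, "/")
    return entry


def _register_builtin_types(registry: ManagedTypeRegistry):
    registry.register(
        "ManagedObjectContainer",
        _container_file_spec,
        populate=None,
        kind="file",
    )
    registry.register(
        "BrainDataMultiFile",
        _multifile_spec,
        populate=None,
        kind="file",
    )


_register_builtin_types(DEFAULT_REGISTRY)
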