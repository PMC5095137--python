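"""Shared test utilities: independent brute-force mapping oracles, random
meta-valid spec-document generation, and small h5py scaffolding.

The oracles here are deliberately written as naive linear scans and gathers,
independent of the package's mapping implementation, so the two routes can
be compared.
"""

from __future__ import annotations

import itertools
import uuid

import h5py
import numpy as np

from managedh5 import (
    AttributeSpec,
    DatasetSpec,
    DimensionSpec,
    FileSpec,
    GroupSpec,
    ManagedRef,
    RelationshipSpec,
    RelationshipTarget,
    RELATIONSHIP_TYPES,
    Selection,
)


def memfile():
    """A fresh in-memory HDF5 file (never touches disk)."""
    return h5py.File(
        uuid.uuid4().hex, "w", driver="core", backing_store=False
    )


# ---------------------------------------------------------------------------
# Brute-force mapping oracles (independent of managedh5.relationships)
# ---------------------------------------------------------------------------


def selection_indices(sel, length):
    """Expand a 1-D selection (selector or Selection) to a plain index list,
    preserving order."""
    if isinstance(sel, Selection):
        if sel.kind == "points":
            return [p[0] for p in sel.point_list]
        sel = sel.selectors[0]
    if isinstance(sel, int):
        return [sel]
    if isinstance(sel, slice):
        return list(range(sel.start, max(sel.stop, sel.start)))
    return list(sel)


def oracle_order(sel_indices, n_source):
    """Identity mapping with bounds check."""
    for i in sel_indices:
        assert 0 <= i < n_source
    return list(sel_indices)


def oracle_indexes(source_values, sel_indices):
    """Gather-then-return: values read from the source at the selected
    positions ARE the target indices, in selection order."""
    return [int(source_values[i]) for i in sel_indices]


def oracle_value_match(source_values, sel_indices, target_values):
    """All target positions whose value equals any selected source value."""
    chosen = {source_values[i] for i in sel_indices}
    return [j for j, v in enumerate(target_values) if v in chosen]


def oracle_range_match(source_values, sel_indices, target_values):
    """All target positions with value within [min, max] of the selected
    source values."""
    if not sel_indices:
        return []
    vals = [source_values[i] for i in sel_indices]
    lo, hi = min(vals), max(vals)
    return [j for j, v in enumerate(target_values) if lo <= v <= hi]


def oracle_imr_pairs(index_map, fill=-1):
    """Every stored (source position, target position) pair of an N-to-M
    index map laid out as (spatial..., [index axis,] stacking axis)."""
    m = np.asarray(index_map)
    pairs = set()
    # 1-D source, 1-D target: (n, k)
    if m.ndim == 2:
        for i in range(m.shape[0]):
            for v in m[i]:
                if v != fill:
                    pairs.add(((i,), (int(v),)))
        return pairs
    # 2-D source, 2-D target: (r, c, 2, k)
    assert m.ndim == 4 and m.shape[2] == 2
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            for k in range(m.shape[3]):
                pt = (int(m[i, j, 0, k]), int(m[i, j, 1, k]))
                if fill not in pt:
                    pairs.add(((i, j), pt))
    return pairs


def mapped_to_indices(sel):
    """Flatten a mapped 1-D Selection to a plain (order-preserving) list."""
    return selection_indices(sel, None) if True else None


def mapped_to_points(sel):
    """Flatten a mapped Selection to a set of coordinate tuples."""
    if sel.kind == "points":
        return set(sel.point_list)
    if sel.kind == "axes" and len(sel.selectors) == 1:
        return {(i,) for i in selection_indices(sel, None)}
    raise AssertionError(f"unexpected mapped selection {sel!r}")


# ---------------------------------------------------------------------------
# Random selections and relationship trial harness
# ---------------------------------------------------------------------------


def random_selection(rng, n):
    """A random 1-D selection: point, half-open range, or index list."""
    kind = rng.integers(0, 3)
    if kind == 0:
        return Selection.axes((int(rng.integers(0, n)),))
    if kind == 1:
        a = int(rng.integers(0, n))
        b = int(rng.integers(a, n + 1))
        return Selection.axes((slice(a, b),))
    size = int(rng.integers(1, min(n, 8) + 1))
    return Selection.axes(
        (tuple(int(i) for i in rng.integers(0, n, size=size)),)
    )


def make_relationship(f, rng, rtype, uid):
    """Random small (source, target) dataset pair plus a stored relationship
    of the given type; returns (rel, source values, target values)."""
    from managedh5 import RelationshipDescriptor, create_relationship_attribute

    n_src = int(rng.integers(1, 51))
    n_tgt = int(rng.integers(1, 51))
    if rtype in ("order", "equivalent"):
        n_tgt = n_src
        src_vals = rng.integers(0, 10, size=n_src)
        tgt_vals = rng.integers(0, 10, size=n_tgt)
    elif rtype == "indexes":
        src_vals = rng.integers(0, n_tgt, size=n_src)
        tgt_vals = rng.integers(0, 100, size=n_tgt)
    elif rtype == "shared_ascending_encoding":
        src_vals = np.sort(rng.integers(0, 40, size=n_src))
        tgt_vals = np.sort(rng.integers(0, 40, size=n_tgt))
    else:  # shared_encoding, indexes_values, user
        src_vals = rng.integers(0, 12, size=n_src)
        tgt_vals = rng.integers(0, 12, size=n_tgt)
    a = f.create_dataset(f"a{uid}", data=src_vals)
    b = f.create_dataset(f"b{uid}", data=tgt_vals)
    rel = create_relationship_attribute(
        a,
        f"r{uid}",
        RelationshipDescriptor(
            relationship_type=rtype,
            source_axes=[0],
            target=RelationshipTarget(location=b.name, axes=[0]),
        ),
    )
    return rel, src_vals, tgt_vals


def check_mapping_against_oracle(rel, sel, src_vals, tgt_vals):
    """Compare map_selection with the brute-force oracle for one trial."""
    from managedh5 import map_selection

    rtype = rel.relationship_type
    idx = selection_indices(sel, len(src_vals))
    mapped = map_selection(rel, sel)
    if rtype in ("order", "equivalent"):
        expected = oracle_order(idx, len(src_vals))
        got = selection_indices(mapped, len(tgt_vals))
        assert got == expected, (rtype, idx, got, expected)
    elif rtype == "indexes":
        expected = oracle_indexes(src_vals, idx)
        got = selection_indices(mapped, len(tgt_vals))
        assert got == expected, (rtype, idx, got, expected)
    elif rtype in ("shared_encoding", "indexes_values"):
        expected = oracle_value_match(src_vals, idx, tgt_vals)
        got = selection_indices(mapped, len(tgt_vals))
        assert got == expected, (rtype, idx, got, expected)
    elif rtype == "shared_ascending_encoding":
        if all(isinstance(s, slice) for s in sel.selectors):
            expected = oracle_range_match(src_vals, idx, tgt_vals)
        else:
            expected = oracle_value_match(src_vals, idx, tgt_vals)
        got = selection_indices(mapped, len(tgt_vals))
        assert got == expected, (rtype, idx, got, expected)
    else:
        raise AssertionError(rtype)


# ---------------------------------------------------------------------------
# Random meta-valid specification documents
# ---------------------------------------------------------------------------

_WORDS = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]


def _rand_name(rng):
    return f"{_WORDS[rng.integers(0, len(_WORDS))]}_{rng.integers(0, 1000)}"


def random_attribute_spec(rng):
    use_prefix = bool(rng.integers(0, 2))
    return AttributeSpec(
        attribute=None if use_prefix else _rand_name(rng),
        prefix=_rand_name(rng) + "_" if use_prefix else None,
        value=_rand_name(rng) if rng.integers(0, 2) else None,
        optional=bool(rng.integers(0, 2)),
        description=_rand_name(rng),
    )


def random_relationship_spec(rng):
    shape = rng.integers(0, 4)
    if shape == 0:
        src = tgt = None
    elif shape == 1:
        src, tgt = int(rng.integers(0, 4)), int(rng.integers(0, 4))
    elif shape == 2:
        n = int(rng.integers(1, 4))
        src = [int(i) for i in rng.integers(0, 5, size=n)]
        tgt = [int(i) for i in rng.integers(0, 5, size=n)]
    else:
        keys = [f"k{i}" for i in range(int(rng.integers(1, 4)))]
        src = {k: int(rng.integers(0, 5)) for k in keys}
        tgt = {k: int(rng.integers(0, 5)) for k in keys}
    return RelationshipSpec(
        attribute=_rand_name(rng),
        relationship_type=RELATIONSHIP_TYPES[
            rng.integers(0, len(RELATIONSHIP_TYPES))
        ],
        optional=bool(rng.integers(0, 2)),
        description=_rand_name(rng),
        properties={"note": _rand_name(rng)} if rng.integers(0, 2) else {},
        source_axes=src,
        target=RelationshipTarget(location="/" + _rand_name(rng), axes=tgt),
    )


def random_dataset_spec(rng):
    use_prefix = bool(rng.integers(0, 2))
    ds = DatasetSpec(
        dataset=None if use_prefix else _rand_name(rng),
        prefix=_rand_name(rng) + "_" if use_prefix else None,
        optional=bool(rng.integers(0, 2)),
        primary=bool(rng.integers(0, 2)),
        description=_rand_name(rng),
    )
    for _ in range(rng.integers(0, 3)):
        try:
            ds.add_attribute(random_attribute_spec(rng))
        except Exception:
            pass
    for i in range(rng.integers(0, 3)):
        try:
            ds.add_dimension(
                DimensionSpec(
                    name=_rand_name(rng),
                    unit="unit",
                    dataset=_rand_name(rng),
                    axis=int(rng.integers(0, 3)),
                    description=_rand_name(rng),
                )
            )
        except Exception:
            pass
    for _ in range(rng.integers(0, 2)):
        try:
            ds.add_relationship(random_relationship_spec(rng))
        except Exception:
            pass
    return ds


def random_group_spec(rng, depth=2):
    use_prefix = bool(rng.integers(0, 2))
    g = GroupSpec(
        group=None if use_prefix else _rand_name(rng),
        prefix=_rand_name(rng) + "_" if use_prefix else None,
        optional=bool(rng.integers(0, 2)),
        description=_rand_name(rng),
    )
    for i in range(rng.integers(0, 3)):
        try:
            g.add_dataset(random_dataset_spec(rng), f"d{i}_{_rand_name(rng)}")
        except Exception:
            pass
    if depth > 0:
        for i in range(rng.integers(0, 3)):
            try:
                g.add_group(
                    random_group_spec(rng, depth - 1), f"g{i}_{_rand_name(rng)}"
                )
            except Exception:
                pass
    for _ in range(rng.integers(0, 2)):
        try:
            g.add_managed(
                ManagedRef(
                    managed_type=_rand_name(rng),
                    optional=bool(rng.integers(0, 2)),
                )
            )
        except Exception:
            pass
    for _ in range(rng.integers(0, 2)):
        try:
            g.add_attribute(random_attribute_spec(rng))
        except Exception:
            pass
    return g


def random_spec_document(rng):
    """A random meta-valid specification document (group, dataset, or file)."""
    kind = rng.integers(0, 3)
    if kind == 0:
        return random_dataset_spec(rng)
    if kind == 1:
        return random_group_spec(rng)
    f = FileSpec(description=_rand_name(rng))
    inner = random_group_spec(rng, depth=1)
    f.add_group(inner, inner.key())
    return f


# ---------------------------------------------------------------------------
# Exhaustive tree-walk oracle for managed-object discovery
# ---------------------------------------------------------------------------


def walk_managed_paths(h5, type_attr="MANAGED_TYPE"):
    """Exhaustive walk collecting (path, stored type) for every object below
    the root that carries the managed-type attribute."""
    out = []

    def visit(group, base):
        for name in sorted(group):
            try:
                child = group[name]
            except KeyError:
                continue
            path = (base.rstrip("/") + "/" + name) if base != "/" else "/" + name
            t = child.attrs.get(type_attr)
            if t is not None:
                if isinstance(t, bytes):
                    t = t.decode()
                out.append((path, t))
            if isinstance(child, h5py.Group):
                visit(child, path)

    visit(h5["/"], "/")
    return out
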