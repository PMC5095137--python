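"""Registry of managed object types.

Each entry maps a type name to a specification factory, a populate procedure
run at creation time, an optional base type (single inheritance), and the
handle class used when wrapping stored objects of that type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

from .errors import RegistryError, SpecValidationError
from .spec import validate_spec_document

__all__ = ["ManagedType", "ManagedTypeRegistry", "DEFAULT_REGISTRY"]


@dataclass
class ManagedType:
    name: str
    spec_factory: Callable[[], object]
    populate: Optional[Callable] = None
    base: Optional[str] = None
    kind: str = "group"  # file | group | dataset
    handle_class: Optional[type] = None


class ManagedTypeRegistry:
    """Mutable mapping of type name -> :class:`ManagedType`."""

    def __init__(self):
        self._types: Dict[str, ManagedType] = {}

    # -- registration ---------------------------------------------------------
    def register(
        self,
        name: str,
        spec_factory: Callable[[], object],
        populate: Optional[Callable] = None,
        base: Optional[str] = None,
        kind: str = "group",
        handle_class: Optional[type] = None,
    ) -> ManagedType:
        """Register a new managed type.

        The spec factory is invoked once immediately and its output
        meta-validated; a failing spec aborts registration with the report
        attached.
        """
        if name in self._types:
            raise RegistryError(f"managed type {name!r} is already registered")
        if base is not None and base not in self._types:
            raise RegistryError(f"base type {base!r} is not registered")
        if kind not in ("file", "group", "dataset"):
            raise RegistryError(f"invalid managed-object kind {kind!r}")
        spec = spec_factory()
        report = validate_spec_document(spec)
        errors = [f for f in report if f["severity"] == "error"]
        if errors:
            raise SpecValidationError(
                f"spec factory for {name!r} produced an invalid specification",
                report=report,
            )
        entry = ManagedType(
            name=name,
            spec_factory=spec_factory,
            populate=populate,
            base=base,
            kind=kind,
            handle_class=handle_class,
        )
        self._types[name] = entry
        return entry

    # -- lookup ---------------------------------------------------------------
    def has(self, name: str) -> bool:
        return name in self._types

    def get(self, name: str) -> ManagedType:
        try:
            return self._types[name]
        except KeyError:
            raise RegistryError(f"managed type {name!r} is not registered") from None

    def spec(self, name: str):
        """A fresh basic specification for ``name`` (factory re-invoked)."""
        return self.get(name).spec_factory()

    def names(self) -> List[str]:
        return list(self._types)

    def __len__(self) -> int:
        return len(self._types)

    def __contains__(self, name: str) -> bool:
        return self.has(name)

    # -- inheritance ----------------------------------------------------------
    def ancestors(self, name: str) -> List[str]:
        """Base-type chain of ``name``, nearest first (excluding ``name``)."""
        chain = []
        cur = self.get(name).base
        while cur is not None:
            if cur in chain:  # defensive; register() prevents cycles
                raise RegistryError(f"cyclic inheritance chain at {cur!r}")
            chain.append(cur)
            cur = self.get(cur).base
        return chain

    def is_subtype(self, name: str, base: str) -> bool:
        """True if ``name`` equals ``base`` or derives from it."""
        if not self.has(name):
            return False
        return name == base or base in self.ancestors(name)

    def handle_class_for(self, name: str):
        """Nearest handle class along the inheritance chain, or None."""
        for t in [name] + self.ancestors(name):
            hc = self.get(t).handle_class
            if hc is not None:
                return hc
        return None


#: Process-wide default registry; application formats register into it on import.
DEFAULT_REGISTRY = ManagedTypeRegistry()
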