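"""Exception hierarchy for managedh5."""


class ManagedH5Error(Exception):
    """Base class for all managedh5 errors."""


class SpecError(ManagedH5Error):
    """A specification document is structurally unusable."""


class SpecValidationError(SpecError):
    """A specification document failed meta-validation.

    Carries the full validation report in ``report``.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report or []


class SpecKindError(SpecError):
    """A child specification of an illegal kind was attached to a parent."""


class SpecCollisionError(SpecError):
    """A child specification key collides with an existing one."""


class SpecResolutionError(SpecError):
    """A managed-type reference could not be resolved against the registry."""

    def __init__(self, message, ref_path=None):
        super().__init__(message)
        self.ref_path = ref_path


class SpecCycleError(SpecError):
    """Recursive spec compilation hit a cyclic managed-type reference."""

    def __init__(self, message, cycle=None):
        super().__init__(message)
        self.cycle = list(cycle or [])


class SpecParseError(SpecError):
    """JSON text could not be parsed into a specification document."""


class RegistryError(ManagedH5Error):
    """Managed-type registration failed."""


class CreationError(ManagedH5Error):
    """Managed-object creation failed (the partial object has been removed)."""


class ObjectLookupError(ManagedH5Error, KeyError):
    """A referenced HDF5 object or relationship leg does not exist."""

    def __str__(self):  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class VerificationError(ManagedH5Error):
    """Compliance verification could not be carried out at all.

    Distinct from a non-compliant result, which is reported, not raised.
    """


class RelationshipError(ManagedH5Error):
    """Invalid relationship descriptor or relationship operation."""


class NoImpliedMappingError(RelationshipError):
    """The relationship type does not imply a selection mapping (user type)."""


class SelectionError(ManagedH5Error):
    """A selection is malformed or incompatible with the relationship."""


class SelectionBoundsError(SelectionError, IndexError):
    """A selection addresses positions outside the source extent."""


class AutoExpandError(ManagedH5Error):
    """Append requested on a group not created in auto-expand mode."""


class ViolationError(ManagedH5Error):
    """The requested violation kind is inapplicable to the given file."""
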