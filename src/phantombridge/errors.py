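"""Exception hierarchy shared across the package."""


class PhantomBridgeError(Exception):
    """Base class for all errors raised by phantombridge."""


class RegistryError(PhantomBridgeError):
    """A bundled or user-supplied region registry failed to load or validate."""


class UnknownRegionError(PhantomBridgeError):
    """A region name did not resolve in the catalog.

    Carries nearest-candidate suggestions to make typos easy to fix.
    """

    def __init__(self, name: str, phantom: str, candidates: list[str] | None = None):
        self.name = name
        self.phantom = phantom
        self.candidates = candidates or []
        msg = f"unknown region {name!r} in {phantom} catalog"
        if self.candidates:
            msg += f"; did you mean: {', '.join(self.candidates)}?"
        super().__init__(msg)


class AmbiguousNameError(PhantomBridgeError):
    """A region name matched more than one catalog entry."""


class UnknownMassError(PhantomBridgeError):
    """An operation required a region mass that the registry does not record."""


class PhantomMismatchError(PhantomBridgeError):
    """An operation received a vector tagged with the wrong phantom."""


class MappingError(PhantomBridgeError):
    """A TIA vector could not be ported under the requested policy."""


class ValidationError(PhantomBridgeError):
    """Input values violated an operation's preconditions."""


class ParseError(PhantomBridgeError):
    """A CSV input failed to parse; reports the offending line."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = path
        self.lineno = lineno
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


class DoseError(PhantomBridgeError):
    """The dose engine could not resolve a required S value or SAF."""
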