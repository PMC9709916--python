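"""Exception hierarchy shared across the package."""


class TorsionForgeError(Exception):
    """Base class for all package errors."""


class InputError(TorsionForgeError):
    """Malformed user input (SMILES/SDF/SMARTS/file schema)."""


class UsageError(TorsionForgeError):
    """An operation was called outside its contract (e.g. non-rotatable bond)."""


class ConsistencyError(TorsionForgeError):
    """Internal cross-references (atom maps, parameter tables) disagree."""


class BackendError(TorsionForgeError):
    """A pluggable provider (bond orders, energies) failed; carries context."""


class CoverageError(TorsionForgeError):
    """A force field failed to assign a parameter to some torsion quartet."""
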