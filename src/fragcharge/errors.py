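"""Exception hierarchy for fragcharge."""


class FragchargeError(Exception):
    """Base class for all package errors."""


class StructuralError(FragchargeError):
    """A structure violates a requirement (missing backbone atom, ...)."""


class ChargeLookupError(FragchargeError):
    """Reference charge table cannot resolve one or more atoms."""

    def __init__(self, unmapped):
        self.unmapped = list(unmapped)
        pairs = ", ".join(f"{r}/{a}" for r, a in self.unmapped)
        super().__init__(f"no reference charge for atoms: {pairs}")


class FragmentationError(FragchargeError):
    """Fragmentation preconditions violated."""


class GeometryError(FragchargeError):
    """Degenerate geometry (zero-length bond vector, clash, ...)."""


class FitError(FragchargeError):
    """ESP fit is ill-posed or inconsistent."""


class GridError(FragchargeError):
    """Grid construction failed (empty grid, bad bounds, ...)."""


class PBError(FragchargeError):
    """Poisson-Boltzmann solve failed (non-convergence, bad setup)."""


class ConfigError(FragchargeError):
    """Configuration schema violation; message carries the field path."""


class ConstructionError(FragchargeError):
    """A requested fixture cannot be built."""
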