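"""Pipeline parameters shared by tagging, convolution, gap estimation and assembly."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Params:
    """Tunable parameters of the gapped-assembly pipeline.

    Attributes
    ----------
    k : int
        Tag length (number of residues per tag). Default 4.
    epsilon : float
        Mass tolerance for tag generation, in Da. Peak-mass differences must
        match a residue mass within ``2 * epsilon``. Default 0.004 (4 mDa).
    g_max : float
        Maximum acceptable gap size, in Da. Binned offset differences above
        this are never reported as gap estimates. Default 3000.
    b_min : int
        Minimum multiplicity a binned offset difference needs to be
        considered as a gap candidate. Default 20.
    a_min : int
        Minimum number of amino acids that supporting tags must jointly cover
        in each of the two strings being joined. Default 6.
    eps_abs_ppm : float
        Relative tolerance, in ppm, for comparing mass offsets during the
        embedding overlap check. Default 10.
    h : int
        Scaling exponent for offset-difference binning: differences are
        multiplied by ``10**h`` before integer rounding. Default 4.
    remove_water_losses : bool
        Whether preprocessing eliminates water-loss ions. Default True.
    reflect : bool
        Whether preprocessing adds precursor-reflected peaks. Default True.
    same_spectrum_only : bool
        Whether tag convolution only pairs tags from the same spectrum
        (the top-down default). Default True.
    """

    k: int = 4
    epsilon: float = 0.004
    g_max: float = 3000.0
    b_min: int = 20
    a_min: int = 6
    eps_abs_ppm: float = 10.0
    h: int = 4
    remove_water_losses: bool = True
    reflect: bool = True
    same_spectrum_only: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.b_min < 1:
            raise ValueError("b_min must be >= 1")
        if self.a_min < self.k:
            raise ValueError("a_min must be >= k")
        if self.eps_abs_ppm <= 0:
            raise ValueError("eps_abs_ppm must be positive")
        if self.h < 0:
            raise ValueError("h must be >= 0")

    @property
    def m_star(self) -> int:
        """Minimum number of distinct supporting tag windows per string."""
        return self.a_min - self.k + 1
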