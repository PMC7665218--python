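"""Helical lattice arithmetic and mass-per-length (MPL) predictions.

A twisted cross-beta fibril is described by a screw operator: an axial
rise (Angstrom) and a twist (degrees) per helical step.  Negative twist
denotes a left-handed helix.  For quasi-2₁ screw symmetry the step maps
one protofilament subunit onto the other, so the twist is close to 180
degrees and the per-dimer (single-subunit) operator is
``(2*rise, 2*twist - 360)``.

Lengths are Angstrom internally; MPL values are reported in kDa/nm with
the unit conversion confined to this module's boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "R_KCAL",
    "HelicalParams",
    "MassModel",
    "ThermoParams",
    "SpiralModel",
    "crossover_period",
    "effective_dimer_operator",
    "quasi21_from_dimer",
    "mpl_from_rise",
    "expected_crossbeta_mpl",
    "subunit_count_from_mpl",
    "SubunitCount",
    "spiral_path_length",
    "strained_spacing",
    "StrainResult",
    "entropy_penalty",
    "ddG_from_ratio",
    "ddG_from_solubility",
    "Measurement",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872041e-3

QUASI_21 = "quasi-21"
_SYMMETRIES = ("C1", QUASI_21, "C2")


def wrap_angle(deg: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = math.fmod(deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class HelicalParams:
    """Screw operator of a helical lattice.

    rise : axial translation per helical step, Angstrom (> 0)
    twist : rotation per step, degrees in (-360, 360]; negative = left-handed
    symmetry : "C1", "quasi-21", or "C2"
    """

    rise: float
    twist: float
    symmetry: str = "C1"

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (-360.0 < self.twist <= 360.0):
            raise ValueError("twist must lie in (-360, 360]")
        if self.symmetry not in _SYMMETRIES:
            raise ValueError(f"symmetry must be one of {_SYMMETRIES}")
        if self.symmetry == QUASI_21 and abs(abs(self.twist) - 180.0) > 90.0:
            raise ValueError("quasi-21 symmetry requires twist near 180 degrees")

    @property
    def left_handed(self) -> bool:
        """Handedness of the per-subunit lattice."""
        if self.symmetry == QUASI_21:
            return wrap_angle(2 * self.twist - 360.0) < 0
        return wrap_angle(self.twist) < 0


def crossover_period(params: HelicalParams) -> float:
    """Axial distance over which the accumulated twist reaches 180 degrees.

    This is the crossover period of a twisted fibril: the cross-section
    rotates by 180 degrees, so the projected width pattern repeats.  For
    quasi-2₁ symmetry the relevant rotation per step is the deviation of
    the twist from 180 degrees, giving ``rise * 180 / |180 - twist|``.

    An untwisted lattice (zero net rotation) has no crossover; the
    function returns ``math.inf`` as a distinct "untwisted" value rather
    than raising.
    """
    if params.symmetry == QUASI_21:
        dev = abs(180.0 - abs(params.twist))
    else:
        dev = abs(wrap_angle(params.twist))
    if dev == 0.0:
        return math.inf
    return params.rise * 180.0 / dev


def effective_dimer_operator(params: HelicalParams) -> HelicalParams:
    """Per-dimer (C1) screw operator equivalent to a quasi-2₁ lattice.

    Two quasi-2₁ steps advance one subunit by one molecule:
    ``(rise, twist)`` -> ``(2*rise, 2*twist - 360)``.
    """
    if params.symmetry != QUASI_21:
        raise ValueError("effective_dimer_operator requires quasi-21 symmetry")
    return HelicalParams(2.0 * params.rise, wrap_angle(2.0 * params.twist - 360.0), "C1")


def quasi21_from_dimer(params: HelicalParams) -> HelicalParams:
    """Inverse of :func:`effective_dimer_operator`."""
    if params.symmetry != "C1":
        raise ValueError("expected a C1 per-dimer operator")
    return HelicalParams(params.rise / 2.0, (params.twist + 360.0) / 2.0, QUASI_21)


@dataclass(frozen=True)
class MassModel:
    """Monomer mass and beta-sheet geometry for MPL arithmetic.

    monomer_mass : kDa
    molecules_per_step : molecules added per helical step
    strand_spacing : beta-sheet repeat distance, nm (0.47-0.48; default 0.48)
    """

    monomer_mass: float
    molecules_per_step: int = 1
    strand_spacing: float = 0.48

    def __post_init__(self) -> None:
        if self.monomer_mass < 0:
            raise ValueError("monomer_mass must be non-negative")
        if self.molecules_per_step < 1:
            raise ValueError("molecules_per_step must be >= 1")
        if self.strand_spacing <= 0:
            raise ValueError("strand_spacing must be positive")


def mpl_from_rise(model: MassModel, params: HelicalParams) -> float:
    """MPL (kDa/nm) implied by a helical lattice with one or more molecules per step."""
    rise_nm = params.rise / 10.0
    return model.monomer_mass * model.molecules_per_step / rise_nm


def expected_crossbeta_mpl(model: MassModel, n_subunits: int = 1) -> float:
    """Expected MPL of ``n_subunits`` cross-beta stacks, one monomer per sheet spacing."""
    if n_subunits < 0:
        raise ValueError("n_subunits must be >= 0")
    return n_subunits * model.monomer_mass / model.strand_spacing


class SubunitCount(NamedTuple):
    count: int
    ratio: float
    ambiguous: bool


def subunit_count_from_mpl(measured: float, model: MassModel) -> SubunitCount:
    """Number of cross-beta subunits implied by a measured MPL.

    The raw ratio of measured MPL to the single-subunit expectation is
    rounded to the nearest integer; a ratio deviating from an integer by
    more than 0.25 is flagged ambiguous (the count is still returned).
    A tie at a half-integer ratio breaks toward the smaller count and is
    always flagged.
    """
    if measured <= 0:
        raise ValueError("measured MPL must be positive")
    ratio = measured / expected_crossbeta_mpl(model, 1)
    frac = ratio - math.floor(ratio)
    if frac == 0.5:
        return SubunitCount(int(math.floor(ratio)), ratio, True)
    count = int(math.floor(ratio + 0.5))
    return SubunitCount(count, ratio, abs(ratio - count) > 0.25)


@dataclass(frozen=True)
class SpiralModel:
    """Geometry of a core forced onto a spiral path by a twisted neighbour.

    twist_period_L : axial distance for a full 360-degree turn, nm
    core_radius_R : radius of the spiral path, nm
    base_spacing : unstrained beta-sheet spacing, Angstrom (default 4.8)
    """

    twist_period_L: float
    core_radius_R: float
    base_spacing: float = 4.8

    def __post_init__(self) -> None:
        if self.twist_period_L <= 0:
            raise ValueError("twist period must be positive")
        if self.core_radius_R < 0:
            raise ValueError("radius must be non-negative")
        if self.base_spacing <= 0:
            raise ValueError("base_spacing must be positive")


def spiral_path_length(spiral: SpiralModel) -> float:
    """Arc length (nm) of one helical turn: sqrt(L^2 + 4 pi^2 R^2)."""
    L, R = spiral.twist_period_L, spiral.core_radius_R
    return math.sqrt(L * L + 4.0 * math.pi * math.pi * R * R)


class StrainResult(NamedTuple):
    factor: float              # rounded-path convention: round(path)/L
    spacing: float             # base_spacing * factor, Angstrom
    factor_exact: float        # path/L
    spacing_exact: float       # base_spacing * factor_exact, Angstrom
    path_length: float         # nm


def strained_spacing(spiral: SpiralModel) -> StrainResult:
    """Strain factor and stretched sheet spacing for a spiral-path core.

    ``factor`` follows the convention of quoting the path length rounded
    to integer nanometres (e.g. 95/88 = 1.08); the exact, unrounded
    factor is also returned.
    """
    path = spiral_path_length(spiral)
    L = spiral.twist_period_L
    exact = path / L
    rounded = round(path) / L
    return StrainResult(
        factor=rounded,
        spacing=spiral.base_spacing * rounded,
        factor_exact=exact,
        spacing_exact=spiral.base_spacing * exact,
        path_length=path,
    )


@dataclass(frozen=True)
class ThermoParams:
    """Inputs for the free-energy estimates.

    temperature : K (default 298.15; sample conditions of ~24 C suggest
        ~297 K -- pass it explicitly for that convention)
    gas_constant : kcal/(mol K)
    solubilities : optional pair of equilibrium solubilities (molar), the
        first being the less stable (more soluble) species
    volume_reduction_factor : count of conformations lost on tethering
    radius_of_gyration : Angstrom, context only
    """

    temperature: float = 298.15
    gas_constant: float = R_KCAL
    solubilities: tuple[float, float] | None = None
    volume_reduction_factor: float | None = None
    radius_of_gyration: float = 30.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.solubilities is not None and any(s <= 0 for s in self.solubilities):
            raise ValueError("solubilities must be positive")
        if self.volume_reduction_factor is not None and self.volume_reduction_factor < 1:
            raise ValueError("volume_reduction_factor must be >= 1")


class Measurement(NamedTuple):
    value: float
    sd: float


def entropy_penalty(thermo: ThermoParams) -> float:
    """Configurational-entropy free-energy cost RT ln(factor), kcal/mol."""
    if thermo.volume_reduction_factor is None:
        raise ValueError("volume_reduction_factor not set")
    return thermo.gas_constant * thermo.temperature * math.log(thermo.volume_reduction_factor)


def ddG_from_ratio(
    ratio: float,
    ratio_sd: float = 0.0,
    temperature: float = 298.15,
    gas_constant: float = R_KCAL,
) -> Measurement:
    """Free-energy difference RT ln(ratio) from a solubility ratio, kcal/mol.

    The uncertainty is propagated from the ratio's standard deviation in
    the first-order (delta-method) approximation RT * (sd_ratio / ratio).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rt = gas_constant * temperature
    return Measurement(rt * math.log(ratio), rt * ratio_sd / ratio)


def ddG_from_solubility(
    thermo: ThermoParams, ratio_sd: float | None = None
) -> Measurement:
    """Free-energy difference RT ln(s1/s2) from a solubility pair, kcal/mol.

    Equilibrium-solubility measurements are often summarized as a mean
    ratio over experiments rather than the ratio of mean solubilities;
    use :func:`ddG_from_ratio` for that convention.
    """
    if thermo.solubilities is None:
        raise ValueError("solubilities not set")
    s1, s2 = thermo.solubilities
    return ddG_from_ratio(
        s1 / s2, ratio_sd or 0.0, thermo.temperature, thermo.gas_constant
    )
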