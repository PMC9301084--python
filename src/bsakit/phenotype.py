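"""Leaf-phenotyping calculators: pigments, chlorophyll fluorescence, qPCR.

Pigment contents come from acetone/ethanol-extract absorbances at 663, 645
and 470 nm via the Arnon-style equations used for maize leaf extracts:

    Chl a (mg/g) = (12.72*OD663 - 2.69*OD645) * V*N/W
    Chl b (mg/g) = (22.88*OD645 - 4.68*OD663) * V*N/W
    Chls  (mg/g) = Chl a + Chl b
    Car   (mg/g) = [OD470*(V/W) - 3.27*Chl a - 104*Chl b] / 198

with V the extract volume (ml), N the dilution factor and W the fresh
weight (g). The carotenoid equation is applied exactly as written above —
note it carries no dilution factor and a 104 coefficient, unlike the
common Lichtenthaler form; a ``variant="lichtenthaler"`` switch is
available for comparison.

Fluorescence parameters are the MultispeQ-style set (relative chlorophyll,
Fv/Fm, Phi2, qL, PhiNPQ, gH+ = 1/tau, and the active-PSI ratio PM/P0).
Relative expression uses the 2^-ddCt method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import mean, stdev

__all__ = [
    "AbsorbanceReading",
    "PigmentContents",
    "FluorescenceTrace",
    "FluorescenceParams",
    "QPCRMeasurement",
    "RelativeExpression",
    "pigments_from_absorbance",
    "fluorescence_params",
    "ddct_relative_expression",
]


@dataclass(frozen=True)
class AbsorbanceReading:
    """Spectrophotometer absorbances plus extraction bookkeeping.

    od663/od645/od470 are unitless absorbances; volume_ml is the leach
    liquor volume V, dilution the dilution factor N, weight_g the fresh
    weight W.
    """

    od663: float
    od645: float
    od470: float
    volume_ml: float
    dilution: float = 1.0
    weight_g: float = 1.0

    def __post_init__(self) -> None:
        for name in ("od663", "od645", "od470"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.volume_ml <= 0:
            raise ValueError("extract volume must be > 0")
        if self.weight_g <= 0:
            raise ValueError("fresh weight must be > 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class PigmentContents:
    """Pigment contents in mg per g fresh weight; chls == chl_a + chl_b."""

    chl_a: float
    chl_b: float
    car: float

    @property
    def chls(self) -> float:
        return self.chl_a + self.chl_b


def pigments_from_absorbance(
    r: AbsorbanceReading, *, variant: str = "printed"
) -> PigmentContents:
    """Compute Chl a, Chl b, total Chls and carotenoid contents (mg/g).

    ``variant="printed"`` applies the equations in the module docstring
    verbatim. ``variant="lichtenthaler"`` swaps the carotenoid equation for
    the Lichtenthaler/Wellburn form
    ``(1000*OD470*V*N/W - 1.82*Chl a - 85.02*Chl b)/198`` for comparison.
    Negative contents are returned as-is with a warning, never clamped.
    """
    scale = r.volume_ml * r.dilution / r.weight_g
    chl_a = (12.72 * r.od663 - 2.69 * r.od645) * scale
    chl_b = (22.88 * r.od645 - 4.68 * r.od663) * scale
    if variant == "printed":
        car = (
            r.od470 * (r.volume_ml / r.weight_g) - 3.27 * chl_a - 104.0 * chl_b
        ) / 198.0
    elif variant == "lichtenthaler":
        car = (1000.0 * r.od470 * scale - 1.82 * chl_a - 85.02 * chl_b) / 198.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out = PigmentContents(chl_a=chl_a, chl_b=chl_b, car=car)
    if chl_a < 0 or chl_b < 0 or car < 0:
        warnings.warn(
            "negative pigment content computed "
            f"(chl_a={chl_a:.4g}, chl_b={chl_b:.4g}, car={car:.4g}); "
            "check the absorbance readings",
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw quantities from a dark/light fluorescence protocol.

    fo/fm: dark-adapted minimal and maximal fluorescence; fs, fm_prime,
    fo_prime: light-adapted steady-state, maximal and minimal; tau: ECS
    decay time constant (s); p_m/p_0: PSI signal quantities; the four
    absorbances feed the relative-chlorophyll estimate scaled by the
    instrument constant k.
    """

    fo: float
    fm: float
    fs: float
    fm_prime: float
    fo_prime: float
    tau: float
    p_m: float
    p_0: float
    abs940: float
    abs650: float
    ref_abs940: float
    ref_abs650: float
    k: float = 1.0

    def validate(self) -> None:
        if not self.fo > 0:
            raise ValueError("Fo must be > 0")
        if self.fm < self.fo:
            raise ValueError("Fm must be >= Fo")
        if not self.fs > 0:
            raise ValueError("Fs must be > 0")
        if self.fm_prime < self.fs:
            raise ValueError("Fm' must be >= Fs")
        if not 0 < self.fo_prime < self.fm_prime:
            raise ValueError("Fo' must satisfy 0 < Fo' < Fm'")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        for name in ("p_m", "p_0", "abs940", "abs650", "ref_abs940",
                     "ref_abs650"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FluorescenceParams:
    """The seven derived photosynthesis parameters."""

    relative_chlorophyll: float
    fv_fm: float
    phi2: float
    ql: float
    phi_npq: float
    g_h_plus: float
    psi_active_fraction: float


def fluorescence_params(t: FluorescenceTrace) -> FluorescenceParams:
    """Derive the photosynthesis parameter set from one trace.

    Fv/Fm = (Fm-Fo)/Fm; Phi2 = (Fm'-Fs)/Fm';
    qL = (Fm'-Fs)/(Fm'-Fo') * Fo'/Fs; PhiNPQ = 1 - Phi2 - Fs/Fm;
    gH+ = 1/tau; active-PSI fraction = PM/P0; relative chlorophyll =
    k * log10[(Abs940 * ref.Abs650) / (Abs650 * ref.Abs940)].
    """
    t.validate()
    phi2 = (t.fm_prime - t.fs) / t.fm_prime
    return FluorescenceParams(
        relative_chlorophyll=t.k
        * math.log10(
            (t.abs940 * t.ref_abs650) / (t.abs650 * t.ref_abs940)
        ),
        fv_fm=(t.fm - t.fo) / t.fm,
        phi2=phi2,
        ql=(t.fm_prime - t.fs) / (t.fm_prime - t.fo_prime) * (t.fo_prime / t.fs),
        phi_npq=1.0 - phi2 - t.fs / t.fm,
        g_h_plus=1.0 / t.tau,
        psi_active_fraction=t.p_m / t.p_0,
    )


@dataclass(frozen=True)
class QPCRMeasurement:
    """Ct replicate lists for target and reference gene in two conditions.

    Replicates are paired by index within each condition (target and
    reference Ct from the same cDNA sample).
    """

    ct_target_treated: tuple[float, ...]
    ct_reference_treated: tuple[float, ...]
    ct_target_control: tuple[float, ...]
    ct_reference_control: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in (
            "ct_target_treated",
            "ct_reference_treated",
            "ct_target_control",
            "ct_reference_control",
        ):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} has no replicates")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} contains non-positive Ct")
        if len(self.ct_target_treated) != len(self.ct_reference_treated):
            raise ValueError("treated target/reference replicate counts differ")
        if len(self.ct_target_control) != len(self.ct_reference_control):
            raise ValueError("control target/reference replicate counts differ")


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt fold change with a propagated spread interval."""

    fold_change: float
    ddct: float
    ddct_se: float
    fold_low: float
    fold_high: float


def ddct_relative_expression(m: QPCRMeasurement) -> RelativeExpression:
    """Relative expression of the target gene by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per replicate pair; ddCt = mean dCt
    (treated) - mean dCt (control); fold change = 2^-ddCt. The spread is
    the fold-change interval at ddCt +/- one combined standard error of
    the two dCt means (zero when a condition has a single replicate).
    """
    dct_t = [a - b for a, b in zip(m.ct_target_treated, m.ct_reference_treated)]
    dct_c = [a - b for a, b in zip(m.ct_target_control, m.ct_reference_control)]
    ddct = mean(dct_t) - mean(dct_c)

    def _sem(values: list[float]) -> float:
        return stdev(values) / math.sqrt(len(values)) if len(values) > 1 else 0.0

    se = math.hypot(_sem(dct_t), _sem(dct_c))
    return RelativeExpression(
        fold_change=2.0 ** (-ddct),
        ddct=ddct,
        ddct_se=se,
        fold_low=2.0 ** (-(ddct + se)),
        fold_high=2.0 ** (-(ddct - se)),
    )
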