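"""Steady-state FRET analysis of k-turn folding.

A duplex RNA carrying the k-turn is labelled with a fluorescein donor
and Cy3 acceptor at the helix termini; kinking brings the ends closer
and raises the FRET efficiency E_FRET.  Titrating with ligand (Mg2+
ions or L7Ae protein) at RNA concentrations comparable to the
dissociation constant requires the tight-binding (ligand-depletion)
isotherm

    E(P_T) = E0 + dE * [(1 + KA*P_T + KA*R_T)
                        - sqrt((1 + KA*P_T + KA*R_T)^2
                               - 4*KA^2*R_T*P_T)] / (2*KA*R_T)

where E0 is the efficiency with no ligand, dE the full amplitude of the
change, KA the apparent association constant (M^-1), and P_T / R_T the
total ligand / RNA concentrations (M).  The bracketed term is the bound
fraction, the smaller root of the mass-balance quadratic, and lies in
[0, 1].

E_FRET itself is measured by the acceptor-(ratio)A normalization
method: the sensitized acceptor emission under donor excitation is
normalized to the directly excited acceptor emission and corrected by
extinction-coefficient ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "SpectrumSet",
    "efret_closed_form",
    "bound_fraction",
    "fit_titration",
    "efret_from_spectra",
    "classify_response",
    "read_titration_csv",
]

#: E_FRET ceiling of the non-folding Mg2+ response (the observed
#: ion-titration curve stays below this across the whole range)
LOW_EFRET_THRESHOLD = 0.18


@dataclass
class TitrationCurve:
    """(P_T, E_FRET) titration data at fixed total RNA concentration."""

    ligand_concentrations: np.ndarray  # P_T, molar
    efret_values: np.ndarray
    rna_total: float  # R_T, molar
    ligand_kind: str = "L7Ae"  # 'Mg2+' | 'L7Ae'
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pt = np.asarray(self.ligand_concentrations, dtype=float)
        ef = np.asarray(self.efret_values, dtype=float)
        if pt.shape != ef.shape:
            raise ValueError("concentration and E_FRET arrays differ in length")
        if np.any(pt < 0) or np.any(np.diff(pt) <= 0):
            raise ValueError("ligand concentrations must be >= 0 and strictly increasing")
        if not self.rna_total > 0:
            raise ValueError("rna_total must be positive")
        if np.any((ef < 0) | (ef > 1)):
            self.flags.append("E_FRET values outside [0, 1]")
        self.ligand_concentrations = pt
        self.efret_values = ef

    def __len__(self) -> int:
        return len(self.ligand_concentrations)


@dataclass
class BindingFit:
    """Least-squares estimates of (E0, dE, KA) with curvature-based SEs."""

    E0: float
    dE: float
    KA: float  # M^-1
    se_E0: float
    se_dE: float
    se_logKA: float  # SE of ln(KA); relative error scale for KA
    rss: float
    converged: bool
    n_points: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.converged:
            if not self.KA > 0:
                raise ValueError("KA must be positive")
            if not math.isfinite(self.dE):
                raise ValueError("dE must be finite")
            if not (-0.5 <= self.E0 <= 1.5):
                self.warnings.append(f"E0 = {self.E0:.3g} outside sanity bounds")

    @property
    def se_KA(self) -> float:
        """Delta-method SE of KA on the linear scale."""
        return self.KA * self.se_logKA

    def ci95(self, df: int | None = None):
        """95% intervals for (E0, dE, ln KA) from a t-distribution."""
        from scipy.stats import t

        df = df if df is not None else max(self.n_points - 3, 1)
        q = t.ppf(0.975, df)
        return {
            "E0": (self.E0 - q * self.se_E0, self.E0 + q * self.se_E0),
            "dE": (self.dE - q * self.se_dE, self.dE + q * self.se_dE),
            "logKA": (math.log(self.KA) - q * self.se_logKA,
                      math.log(self.KA) + q * self.se_logKA),
        }


def bound_fraction(PT, KA: float, RT: float):
    """Bound RNA fraction from the mass-balance quadratic (smaller root)."""
    PT = np.asarray(PT, dtype=float)
    if KA <= 0 or RT <= 0:
        raise ValueError("KA and RT must be positive")
    if np.any(PT < 0):
        raise ValueError("PT must be >= 0")
    s = 1.0 + KA * PT + KA * RT
    rad = s * s - 4.0 * KA * KA * RT * PT
    # round-off can push the radicand slightly negative at saturation
    tol = 1e-8 * np.maximum(s * s, 1.0)
    if np.any(rad < -tol):
        raise FloatingPointError("negative radicand: inconsistent isotherm inputs")
    rad = np.clip(rad, 0.0, None)
    f = (s - np.sqrt(rad)) / (2.0 * KA * RT)
    return np.clip(f, 0.0, 1.0)


def efret_closed_form(PT, E0: float, dE: float, KA: float, RT: float):
    """Tight-binding isotherm: E0 + dE * bound_fraction(PT; KA, RT).

    Exact limits: E(0) = E0; E -> E0 + dE at saturating ligand.
    """
    PT = np.asarray(PT, dtype=float)
    out = E0 + dE * bound_fraction(PT, KA, RT)
    return out if out.ndim else float(out)


def _default_guess(curve: TitrationCurve) -> tuple[float, float, float]:
    """E0 <- min(E); dE <- max - min; KA <- 1 / (P_T at half-amplitude)."""
    e = curve.efret_values
    pt = curve.ligand_concentrations
    e0 = float(np.min(e))
    de = float(np.max(e) - np.min(e))
    half = e0 + 0.5 * de
    above = np.nonzero(e >= half)[0]
    idx = above[0] if len(above) else len(pt) - 1
    p_half = pt[idx] if pt[idx] > 0 else (pt[pt > 0][0] if np.any(pt > 0) else 1.0)
    return e0, de, 1.0 / p_half


def fit_titration(curve: TitrationCurve,
                  initial_guess: tuple[float, float, float] | None = None
                  ) -> BindingFit:
    """Fit (E0, dE, KA) of the tight-binding isotherm to a titration.

    Homoscedastic least squares; KA is optimized as ln(KA) to enforce
    positivity; standard errors come from the Jacobian at the optimum.
    Non-convergence and boundary/identifiability problems are returned
    as flags on the fit, never silently.
    """
    if len(curve) < 4:
        raise ValueError("need at least 4 titration points")
    pt = curve.ligand_concentrations
    e = curve.efret_values
    rt = curve.rna_total
    e0, de, ka = initial_guess or _default_guess(curve)
    ka = max(ka, 1e-6)
    x0 = np.array([e0, max(de, 1e-6), math.log(ka)])

    def resid(x):
        return efret_closed_form(pt, x[0], x[1], math.exp(x[2]), rt) - e

    lo = [-0.5, -2.0, math.log(1e-2)]
    hi = [1.5, 2.0, math.log(1e15)]
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    warnings = []
    converged = bool(sol.success)
    if not converged:
        warnings.append(f"optimizer did not converge: {sol.message}")
    E0f, dEf, logKAf = sol.x
    if logKAf >= hi[2] - 1e-6 or logKAf <= lo[2] + 1e-6:
        warnings.append("KA at optimization boundary")

    rss = float(np.sum(sol.fun ** 2))
    dof = max(len(pt) - 3, 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.inf)
        warnings.append("singular curvature: parameters unidentifiable")
    # an SE above 2 natural-log units means KA is uncertain by more than
    # an order of magnitude either way: effectively unidentifiable
    if not np.all(np.isfinite(ses)) or ses[2] > 2.0:
        warnings.append("KA unidentifiable from these data")

    return BindingFit(
        E0=float(E0f), dE=float(dEf), KA=float(math.exp(logKAf)),
        se_E0=float(ses[0]), se_dE=float(ses[1]), se_logKA=float(ses[2]),
        rss=rss, converged=converged, n_points=len(pt), warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Acceptor-normalization E_FRET from emission spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSet:
    """Emission spectra and extinction ratios for (ratio)A normalization.

    ``donor_excited``: emission spectrum under donor-band excitation
    (donor emission + sensitized and directly excited acceptor
    emission); ``acceptor_excited``: emission under direct acceptor
    excitation; ``donor_only``: reference emission spectrum of a
    donor-only sample (arbitrary scale).  Extinction coefficients are
    inputs, not constants: eps_D(lam_D), eps_A(lam_D), eps_A(lam_A).
    """

    wavelengths: np.ndarray
    donor_excited: np.ndarray
    acceptor_excited: np.ndarray
    donor_only: np.ndarray
    eps_donor_at_donor_ex: float
    eps_acceptor_at_donor_ex: float
    eps_acceptor_at_acceptor_ex: float

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        for name in ("donor_excited", "acceptor_excited", "donor_only"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != w.shape:
                raise ValueError(f"{name} not on the common wavelength grid")
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} has negative intensities")
            setattr(self, name, arr)
        self.wavelengths = w


def efret_from_spectra(spectra: SpectrumSet) -> float:
    """E_FRET by acceptor normalization.

    The donor-excited spectrum is decomposed by linear least squares
    into a scaled donor-only reference plus a scaled copy of the
    directly excited acceptor spectrum; the acceptor coefficient is
    (ratio)A = F_sensitized+direct(A) / F_direct(A).  Then

        E = ((ratio)A - eps_A(lam_D)/eps_A(lam_A)) * eps_A(lam_A)/eps_D(lam_D)

    which removes the direct-excitation contribution of the acceptor at
    the donor excitation wavelength.
    """
    basis = np.column_stack([spectra.donor_only, spectra.acceptor_excited])
    coef, *_ = np.linalg.lstsq(basis, spectra.donor_excited, rcond=None)
    ratio_a = float(coef[1])
    if ratio_a < 0:
        # sensitized emission cannot be negative; clamp and report via value
        import warnings as _w
        _w.warn("negative sensitized acceptor emission; clamped to 0")
        ratio_a = 0.0
    eA_lD = spectra.eps_acceptor_at_donor_ex
    eA_lA = spectra.eps_acceptor_at_acceptor_ex
    eD_lD = spectra.eps_donor_at_donor_ex
    return (ratio_a - eA_lD / eA_lA) * eA_lA / eD_lD


# ---------------------------------------------------------------------------
# Response classification (ion vs protein behaviour)
# ---------------------------------------------------------------------------

@dataclass
class ResponseCall:
    call: str  # non_folding | folding_transition | undetermined
    fit: BindingFit | None
    diagnostics: str


def classify_response(curve: TitrationCurve,
                      low_threshold: float = LOW_EFRET_THRESHOLD) -> ResponseCall:
    """Classify a titration as non-folding vs a folding transition.

    non_folding: E_FRET stays below ``low_threshold`` across the whole
    range (the Mg2+ signature of this UTR k-turn).  folding_transition:
    the isotherm fit converges with dE > 3 SE and a plateau E0 + dE
    above the threshold (the L7Ae signature).  Anything else is
    undetermined, with diagnostics.
    """
    if len(curve) == 0:
        raise ValueError("empty titration curve")
    emax = float(np.max(curve.efret_values))
    if emax < low_threshold:
        return ResponseCall("non_folding", None,
                            f"max E_FRET {emax:.3f} < {low_threshold}")
    fit = None
    if len(curve) >= 4:
        fit = fit_titration(curve)
        plateau = fit.E0 + fit.dE
        if (fit.converged and fit.se_dE > 0
                and fit.dE > 3.0 * fit.se_dE and plateau > low_threshold):
            return ResponseCall(
                "folding_transition", fit,
                f"dE = {fit.dE:.3f} ({fit.dE / fit.se_dE:.1f} SE), "
                f"plateau {plateau:.3f} > {low_threshold}")
    return ResponseCall("undetermined", fit,
                        "neither flat-low nor a significant fitted transition")


def read_titration_csv(path, rna_total: float,
                       ligand_kind: str = "L7Ae") -> TitrationCurve:
    """Read a titration CSV with header columns ``ligand_M, efret``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"ligand_M", "efret"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration CSV must have columns {sorted(required)}")
    return TitrationCurve(df["ligand_M"].to_numpy(), df["efret"].to_numpy(),
                          rna_total=rna_total, ligand_kind=ligand_kind)
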