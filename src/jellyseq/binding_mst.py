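"""Multiphasic binding isotherms, self-association, and least-squares fitting.

The binding-event model is the exact 1:1 ligand-depletion solution

    theta(P; Kd, L) = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 L)

which reduces to the hyperbola P / (P + Kd) as the labeled concentration
L -> 0.  A multiphasic curve is an amplitude-weighted sum of independent
binding events over a shared labeled species.  The number of phases is
selected by BIC.  Self-association is a Hill curve with the Hill
coefficient fixed to 1 unless freed explicitly.

Concentrations are molar throughout; Kd ordering inside a model is
enforced by parameterizing log-Kd gaps during fitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

from .formats import JellyseqError

if TYPE_CHECKING:  # pragma: no cover
    from .synthio import TitrationCurve


class FitError(JellyseqError):
    """A fit could not be set up (not a convergence failure)."""


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingPhase:
    """One independent binding event: dissociation constant and signal span."""

    kd: float  # molar
    amplitude: float  # signal units

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise FitError("kd must be positive")


@dataclass
class BindingModel:
    """Baseline plus a sum of independent ligand-depletion binding events."""

    baseline: float
    phases: tuple[BindingPhase, ...]
    labeled_conc: float  # molar, in-capillary

    def __post_init__(self) -> None:
        self.phases = tuple(sorted(self.phases, key=lambda p: p.kd))
        if self.labeled_conc < 0:
            raise FitError("labeled concentration must be nonnegative")

    @property
    def kds(self) -> np.ndarray:
        return np.array([p.kd for p in self.phases])


@dataclass
class SelfAssocModel:
    """Apparent self-association: Hill curve with cooperativity h >= 1."""

    kd_app: float
    hill: float = 1.0
    s0: float = 0.0
    delta_s: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_app <= 0:
            raise FitError("kd_app must be positive")


@dataclass
class FitResult:
    """Outcome of a least-squares fit with BIC for model comparison."""

    model: BindingModel | SelfAssocModel
    rss: float
    n_points: int
    bic: float
    converged: bool
    n_starts: int = 1
    message: str = ""
    bootstrap_intervals: dict | None = None


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def isotherm(P, kd: float, L: float):
    """Fraction of labeled species bound under 1:1 ligand depletion.

    Evaluated in the cancellation-free form 2P / (S + sqrt(S^2 - 4PL)) with
    S = P + L + Kd, which is exact for L > 0 and continuous at L = 0 where
    it equals P / (P + Kd).
    """
    P = np.asarray(P, dtype=float)
    s = P + L + kd
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)
    denom = s + np.sqrt(disc)
    return np.where(denom > 0, 2.0 * P / np.where(denom > 0, denom, 1.0), 0.0)


def predict(model: BindingModel, protein_concs) -> np.ndarray:
    """Signal of a multiphasic model at the given protein concentrations."""
    protein_concs = np.asarray(protein_concs, dtype=float)
    signal = np.full_like(protein_concs, model.baseline, dtype=float)
    for phase in model.phases:
        signal = signal + phase.amplitude * isotherm(
            protein_concs, phase.kd, model.labeled_conc
        )
    return signal


def hill_signal(concs, kd_app: float, hill: float, s0: float, delta_s: float):
    """Hill-type saturation signal s0 + delta_s * C^h / (Kd^h + C^h)."""
    concs = np.asarray(concs, dtype=float)
    ch = np.power(concs, hill)
    return s0 + delta_s * ch / (np.power(kd_app, hill) + ch)


def predict_self_association(model: SelfAssocModel, concs) -> np.ndarray:
    return hill_signal(concs, model.kd_app, model.hill, model.s0, model.delta_s)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _bic(rss: float, n_points: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n_points * np.log(rss / n_points) + n_params * np.log(n_points)


def _unpack_params(x: np.ndarray, n_phases: int, labeled_conc: float) -> BindingModel:
    baseline = x[0]
    log_kd1 = x[1]
    gaps = x[2 : 1 + n_phases]
    log_kds = log_kd1 + np.concatenate([[0.0], np.cumsum(gaps)])
    amps = x[1 + n_phases :]
    phases = tuple(
        BindingPhase(kd=10.0 ** lk, amplitude=a) for lk, a in zip(log_kds, amps)
    )
    return BindingModel(baseline=baseline, phases=phases, labeled_conc=labeled_conc)


def fit_multiphase(
    curve: "TitrationCurve",
    n_phases: int,
    *,
    labeled_conc: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit an n-phase ligand-depletion model by multi-start least squares.

    Parameters are (baseline, log10 Kd of the tightest phase, nonnegative
    log10-Kd gaps, nonnegative amplitudes); the gap parameterization keeps
    the fitted Kds ordered.  Starts are drawn from a log-spaced Kd lattice
    spanning the titration range; the result is the best local optimum.
    """
    P, y = curve.flat()
    n_params = 2 * n_phases + 1
    if len(y) < 2 * n_params:
        raise FitError(
            f"{n_phases} phases need at least {2 * n_params} data points, got {len(y)}"
        )
    L = curve.labeled_conc if labeled_conc is None else labeled_conc
    rng = np.random.default_rng(seed)

    log_lo = np.log10(P[P > 0].min()) - 1.0
    log_hi = np.log10(P.max()) + 1.0
    span = y.max() - y.min()
    baseline0 = float(y.min())

    def residuals(x: np.ndarray) -> np.ndarray:
        model = _unpack_params(x, n_phases, L)
        return predict(model, P) - y

    lower = np.concatenate(
        [[-np.inf], [log_lo - 2.0], np.zeros(n_phases - 1), np.zeros(n_phases)]
    )
    upper = np.concatenate(
        [[np.inf], [log_hi + 2.0], np.full(n_phases - 1, log_hi - log_lo + 4.0),
         np.full(n_phases, np.inf)]
    )

    starts = []
    # deterministic start: Kds spread evenly across the titration range
    spread = np.linspace(log_lo + 0.5, log_hi - 0.5, n_phases)
    starts.append(spread)
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.sort(rng.uniform(log_lo, log_hi, size=n_phases)))

    best = None
    for start_kds in starts:
        gaps0 = np.maximum(np.diff(start_kds), 0.05)
        amps0 = np.full(n_phases, max(span, 1e-12) / n_phases)
        x0 = np.concatenate([[baseline0], [start_kds[0]], gaps0, amps0])
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitError("all optimizer starts failed")
    rss, sol = best
    model = _unpack_params(sol.x, n_phases, L)
    return FitResult(
        model=model,
        rss=rss,
        n_points=len(y),
        bic=_bic(rss, len(y), n_params),
        converged=bool(sol.success),
        n_starts=len(starts),
        message=sol.message,
    )


def select_phase_count(
    curve: "TitrationCurve",
    max_phases: int,
    *,
    labeled_conc: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[int, dict[int, FitResult]]:
    """Fit 1..max_phases and return the BIC-minimizing phase count."""
    if max_phases < 1:
        raise FitError("max_phases must be at least 1")
    fits: dict[int, FitResult] = {}
    for n in range(1, max_phases + 1):
        try:
            fits[n] = fit_multiphase(
                curve, n, labeled_conc=labeled_conc, n_starts=n_starts, seed=seed
            )
        except FitError:
            break  # too many parameters for the data; larger n only worse
    if not fits:
        raise FitError("no phase count could be fitted")
    best_n = min(fits, key=lambda n: fits[n].bic)
    return best_n, fits


def fit_self_association(
    curve: "TitrationCurve",
    *,
    fit_hill: bool = False,
    n_starts: int = 6,
    seed: int = 0,
) -> FitResult:
    """Fit the apparent self-association Kd (Hill model, h = 1 by default)."""
    C, y = curve.flat()
    if len(y) < 8:
        raise FitError("self-association fit needs at least 8 points")
    rng = np.random.default_rng(seed)
    log_lo = np.log10(C[C > 0].min()) - 1.0
    log_hi = np.log10(C.max()) + 1.0
    span = y.max() - y.min()

    def unpack(x: np.ndarray) -> SelfAssocModel:
        hill = x[3] if fit_hill else 1.0
        return SelfAssocModel(kd_app=10.0 ** x[0], hill=hill, s0=x[1], delta_s=x[2])

    def residuals(x: np.ndarray) -> np.ndarray:
        return predict_self_association(unpack(x), C) - y

    n_params = 4 if fit_hill else 3
    lower = [log_lo - 2.0, -np.inf, -np.inf] + ([1.0] if fit_hill else [])
    upper = [log_hi + 2.0, np.inf, np.inf] + ([6.0] if fit_hill else [])

    best = None
    start_kds = np.concatenate(
        [[0.5 * (log_lo + log_hi)], rng.uniform(log_lo, log_hi, size=max(0, n_starts - 1))]
    )
    for lk in start_kds:
        x0 = [lk, float(y.min()), max(span, 1e-12)] + ([1.0] if fit_hill else [])
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return FitResult(
            model=SelfAssocModel(kd_app=1.0), rss=np.inf, n_points=len(y),
            bic=np.inf, converged=False, message="all starts failed",
        )
    rss, sol = best
    return FitResult(
        model=unpack(sol.x),
        rss=rss,
        n_points=len(y),
        bic=_bic(rss, len(y), n_params),
        converged=bool(sol.success),
        n_starts=len(start_kds),
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# Unit helpers
# ---------------------------------------------------------------------------

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
}


def parse_concentration(value: float | str) -> float:
    """Parse '648 uM' / '4 nM' / a plain molar float into molar units."""
    if isinstance(value, (int, float)):
        return float(value)
    match = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Zµμ]+)\s*", value)
    if not match:
        raise FitError(f"cannot parse concentration {value!r}")
    number, unit = match.groups()
    if unit not in _UNIT_TO_MOLAR:
        raise FitError(f"unknown concentration unit {unit!r}")
    return float(number) * _UNIT_TO_MOLAR[unit]


def concentration_ratio(conc: float | str, kd: float | str) -> float:
    """Fold excess of a concentration over a Kd, after unit normalization."""
    conc_m = parse_concentration(conc)
    kd_m = parse_concentration(kd)
    if conc_m <= 0 or kd_m <= 0:
        raise FitError("concentrations must be positive")
    return conc_m / kd_m


def protein_monomer_mass(sequence: str) -> float:
    """Average molecular mass of a protein sequence in daltons."""
    from Bio.SeqUtils import molecular_weight

    return float(molecular_weight(sequence.replace("*", ""), seq_type="protein"))


def molar_from_mass_concentration(mg_per_ml: float, monomer_mass_da: float) -> float:
    """Convert a mass concentration (mg/mL) to molarity given the monomer mass."""
    if mg_per_ml < 0 or monomer_mass_da <= 0:
        raise FitError("mass concentration and monomer mass must be positive")
    return mg_per_ml / monomer_mass_da  # (g/L) / (g/mol) = mol/L
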