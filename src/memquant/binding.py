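"""Equilibrium binding models and Kd estimation.

Implements the two equilibrium assays used to characterise membrane and
receptor-peptide binding of a cytosolic signaling protein:

* SPR vesicle binding: sensorgram plateaus are normalised to fractional
  occupancy ``RU/RUmax`` and fit to a one-site Langmuir isotherm
  ``RU/RUmax = 1 / (1 + Kd / P0)`` where ``P0`` is the total protein
  concentration (valid because the protein is in large excess over
  binding sites on the vesicle surface).
* Fluorescence anisotropy peptide titrations: anisotropy is normalised to
  ``A_norm = (A - A_min) / (A_max - A_min)`` and fit to the same
  hyperbola, ``A_norm = 1 / (1 + Kd / P0)``, valid in the ligand-excess
  regime ``P0 >> Pep0``.

Both fits optimise log Kd (positivity by construction) with damped least
squares; standard errors come from the local curvature of the residual
surface, with a seeded bootstrap available as an alternative. Downstream
helpers compute fold changes in affinity and selectivity reports from
tables of fitted Kd values.

Units are carried explicitly: lipid-surface Kd values are reported in nM
and peptide Kd values in uM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InvalidInputError

__all__ = [
    "Sensorgram",
    "EquilibriumIsotherm",
    "KdEstimate",
    "AnisotropyTitration",
    "estimate_rumax",
    "steady_state_response",
    "normalize_sensorgram",
    "isotherm_from_sensorgrams",
    "langmuir_fraction",
    "fit_langmuir_kd",
    "fit_anisotropy_kd",
    "affinity_fold_change",
    "selectivity_report",
    "pip2_dose_response",
    "load_reference_kd_table",
]

# Fraction of an association phase treated as the steady-state plateau.
PLATEAU_FRACTION = 0.10
# Responses below this ceiling across a whole isotherm mean "no binding".
NO_BINDING_CEILING = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Sensorgram:
    """One SPR association-phase trace at a single protein concentration.

    Parameters
    ----------
    time:
        Seconds, strictly increasing.
    response:
        Resonance units (RU), same length as ``time``.
    protein_concentration:
        Total protein concentration in nM (must be >= 0).
    lipid_composition:
        Mapping of lipid name to mole percent; mole percents must sum to
        100 +/- 0.01 when provided.
    phase:
        Only ``"association"`` traces are analysed; ``"dissociation"``
        traces are accepted for round-tripping but rejected by the fits.
    """

    time: np.ndarray
    response: np.ndarray
    protein_concentration: float
    lipid_composition: Mapping[str, float] = field(default_factory=dict)
    phase: str = "association"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.response.shape:
            raise InvalidInputError("time and response must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise InvalidInputError("sensorgram time axis must be strictly increasing")
        if self.protein_concentration < 0:
            raise InvalidInputError("protein_concentration must be >= 0")
        if self.lipid_composition:
            total = float(sum(self.lipid_composition.values()))
            if abs(total - 100.0) > 0.01:
                raise InvalidInputError(
                    f"lipid mole percents must sum to 100 +/- 0.01, got {total!r}"
                )
        if self.phase not in ("association", "dissociation"):
            raise InvalidInputError(f"unknown phase {self.phase!r}")


@dataclass
class EquilibriumIsotherm:
    """Normalised steady-state binding data: RU/RUmax versus concentration."""

    surface_id: str
    protein_concentrations: np.ndarray
    normalized_responses: np.ndarray
    replicate_sd: np.ndarray | None = None
    concentration_unit: str = "nM"

    def __post_init__(self) -> None:
        self.protein_concentrations = np.asarray(self.protein_concentrations, dtype=float)
        self.normalized_responses = np.asarray(self.normalized_responses, dtype=float)
        if self.protein_concentrations.shape != self.normalized_responses.shape:
            raise InvalidInputError("concentration and response arrays must have equal length")
        if np.any(self.protein_concentrations < 0):
            raise InvalidInputError("protein concentrations must be non-negative")
        if np.unique(self.protein_concentrations).size < 4:
            raise InvalidInputError("need at least 4 distinct protein concentrations")
        lo, hi = self.normalized_responses.min(), self.normalized_responses.max()
        if lo < -0.05 or hi > 1.10:
            raise InvalidInputError(
                f"normalized responses outside the [-0.05, 1.10] noise band: [{lo:.3g}, {hi:.3g}]"
            )
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if self.replicate_sd.shape != self.normalized_responses.shape:
                raise InvalidInputError("replicate_sd must match the response array length")


@dataclass
class KdEstimate:
    """Result of a one-site Langmuir Kd fit.

    ``kd`` and ``kd_se`` share ``unit`` (nM for lipid surfaces, uM for
    peptides). ``residual_norm`` is the root-sum-square of fit residuals.
    """

    kd: float
    kd_se: float
    unit: str
    n_points: int
    residual_norm: float
    model: str = "langmuir"
    surface_id: str = ""
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise InvalidInputError("kd must be positive")
        if self.kd_se < 0:
            raise InvalidInputError("kd_se must be >= 0")


@dataclass
class AnisotropyTitration:
    """A fluorescence-anisotropy titration of a labelled peptide.

    The labelled peptide is held at a fixed low concentration
    (``peptide_concentration``, nM) while the protein concentration
    (``protein_concentrations``, uM) is varied; ``anisotropy`` holds the
    observed values. Normalised values are computed on demand from
    ``a_min``/``a_max`` (observed extremes unless supplied).
    """

    peptide_id: str
    peptide_concentration: float  # nM, fixed
    protein_concentrations: np.ndarray  # uM
    anisotropy: np.ndarray
    a_min: float | None = None
    a_max: float | None = None

    def __post_init__(self) -> None:
        self.protein_concentrations = np.asarray(self.protein_concentrations, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.protein_concentrations.shape != self.anisotropy.shape:
            raise InvalidInputError("concentration and anisotropy arrays must have equal length")
        if np.any(self.protein_concentrations < 0):
            raise InvalidInputError("protein concentrations must be non-negative")

    def ligand_excess_ok(self) -> bool:
        """True when Pep0 << min positive P0 (both in the same unit)."""
        positive = self.protein_concentrations[self.protein_concentrations > 0]
        if positive.size == 0:
            return False
        # peptide in nM, protein in uM: compare in nM
        return self.peptide_concentration < 0.1 * positive.min() * 1e3

    def normalized(self) -> np.ndarray:
        """``(A - A_min) / (A_max - A_min)`` with supplied or observed extremes."""
        a_min = float(self.anisotropy.min()) if self.a_min is None else self.a_min
        a_max = float(self.anisotropy.max()) if self.a_max is None else self.a_max
        if not a_max > a_min:
            raise InvalidInputError("a_max must exceed a_min for normalization")
        return (self.anisotropy - a_min) / (a_max - a_min)


# ---------------------------------------------------------------------------
# Sensorgram reduction
# ---------------------------------------------------------------------------

def _plateau(time: np.ndarray, response: np.ndarray) -> float:
    n_tail = max(1, int(round(PLATEAU_FRACTION * time.size)))
    return float(np.mean(response[-n_tail:]))


def steady_state_response(s: Sensorgram) -> float:
    """Steady-state RU of one association trace: mean of the final 10% of samples."""
    if s.time.size < 5:
        raise InvalidInputError("sensorgram must have at least 5 time points")
    return _plateau(s.time, s.response)


def estimate_rumax(sensorgrams: Sequence[Sensorgram]) -> tuple[float, float]:
    """Estimate the saturating response RUmax from replicate saturating traces.

    Each sensorgram must be an association phase recorded at a saturating
    protein concentration (e.g. 1 uM). The plateau of each replicate is the
    mean response over its final 10% of time points; RUmax is the mean of
    the replicate plateaus.

    Returns
    -------
    (rumax, sd):
        Mean plateau across replicates and the across-replicate SD
        (0.0 for a single replicate).
    """
    if len(sensorgrams) == 0:
        raise InvalidInputError("need at least one saturating sensorgram")
    plateaus = []
    for s in sensorgrams:
        if s.phase != "association":
            raise InvalidInputError("RUmax estimation requires association-phase sensorgrams")
        plateaus.append(steady_state_response(s))
    plateaus = np.asarray(plateaus)
    sd = float(plateaus.std(ddof=1)) if plateaus.size > 1 else 0.0
    return float(plateaus.mean()), sd


def normalize_sensorgram(s: Sensorgram, rumax: float) -> float:
    """Steady-state fractional occupancy RU/RUmax for one sensorgram."""
    if not rumax > 0:
        raise InvalidInputError("rumax must be positive")
    return steady_state_response(s) / rumax


def isotherm_from_sensorgrams(
    sensorgrams: Sequence[Sensorgram],
    rumax: float,
    surface_id: str = "",
) -> EquilibriumIsotherm:
    """Reduce association sensorgrams at varying concentration to an isotherm.

    Dissociation-phase traces are ignored. Replicates at the same
    concentration are averaged and their SD recorded.
    """
    assoc = [s for s in sensorgrams if s.phase == "association"]
    if not assoc:
        raise InvalidInputError("no association-phase sensorgrams supplied")
    rows: dict[float, list[float]] = {}
    for s in assoc:
        rows.setdefault(s.protein_concentration, []).append(normalize_sensorgram(s, rumax))
    conc = np.array(sorted(rows))
    resp = np.array([np.mean(rows[c]) for c in conc])
    sd = np.array([np.std(rows[c], ddof=1) if len(rows[c]) > 1 else 0.0 for c in conc])
    return EquilibriumIsotherm(surface_id, conc, resp, replicate_sd=sd)


# ---------------------------------------------------------------------------
# Langmuir / anisotropy Kd fitting
# ---------------------------------------------------------------------------

def langmuir_fraction(concentration, kd):
    """One-site Langmuir occupancy: 1 / (1 + Kd / P0); 0 at P0 = 0."""
    c = np.asarray(concentration, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(c > 0, 1.0 / (1.0 + kd / np.where(c > 0, c, 1.0)), 0.0)
    return out


def _fit_log_kd(
    conc: np.ndarray,
    resp: np.ndarray,
    weights: np.ndarray | None,
    free_amplitude: bool = False,
) -> tuple[float, float, float]:
    """Damped least squares on log10 Kd. Returns (kd, kd_se, residual_norm).

    With ``free_amplitude`` the model is ``amp / (1 + Kd/P0)``, profiling
    out the saturation amplitude (closed-form linear sub-problem); the
    default fixes amp = 1, the fully normalised occupancy model.
    """
    if np.max(np.abs(resp)) < NO_BINDING_CEILING:
        raise FitError(
            "no binding detected: all normalized responses are below "
            f"{NO_BINDING_CEILING}; a Langmuir Kd is unidentifiable"
        )
    w = np.ones_like(resp) if weights is None else np.asarray(weights, dtype=float)
    w = np.where(w > 0, w, np.nanmin(w[w > 0]) if np.any(w > 0) else 1.0)

    def _amp(kd: float) -> float:
        if not free_amplitude:
            return 1.0
        f = langmuir_fraction(conc, kd) / w
        denom = float(f @ f)
        return float(f @ (resp / w)) / denom if denom > 0 else 1.0

    def residuals(log10_kd: np.ndarray) -> np.ndarray:
        kd = 10.0 ** log10_kd[0]
        return (_amp(kd) * langmuir_fraction(conc, kd) - resp) / w

    # crude half-saturation initialiser
    half = np.argmin(np.abs(resp - 0.5))
    x0 = math.log10(max(conc[half], 1e-6))
    sol = optimize.least_squares(residuals, x0=[x0], method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError(f"Langmuir fit failed to converge: {sol.message}")
    log10_kd = sol.x[0]
    kd = 10.0 ** log10_kd
    # SE from the local curvature (Gauss-Newton Hessian) of the residual surface
    n, p = resp.size, 2 if free_amplitude else 1
    dof = max(n - p, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = float((sol.jac.T @ sol.jac).item())
    se_log10 = math.sqrt(s2 / jtj) if jtj > 0 else math.inf
    kd_se = kd * math.log(10.0) * se_log10
    residual_norm = float(np.linalg.norm(residuals(sol.x) * w))
    return kd, kd_se, residual_norm


def _bootstrap_kd_se(
    conc: np.ndarray, resp: np.ndarray, weights: np.ndarray | None,
    n_boot: int, seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    kds = []
    n = conc.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(conc[idx]).size < 2:
            continue
        try:
            kd, _, _ = _fit_log_kd(conc[idx], resp[idx],
                                   None if weights is None else weights[idx])
        except FitError:
            continue
        kds.append(kd)
    return float(np.std(kds, ddof=1)) if len(kds) > 1 else math.inf


def fit_langmuir_kd(
    iso: EquilibriumIsotherm,
    weights: np.ndarray | None = None,
    se_method: str = "curvature",
    n_boot: int = 1000,
    seed: int = 0,
) -> KdEstimate:
    """Fit a one-site Langmuir isotherm, RU/RUmax = 1/(1 + Kd/P0).

    Kd is optimised on a log scale (positive by construction) by damped
    nonlinear least squares; the fit is invariant to the ordering of the
    concentration points. ``weights`` (e.g. replicate SDs) divide the
    residuals. ``se_method`` is ``"curvature"`` (inverse local curvature
    at the optimum) or ``"bootstrap"`` (seeded case resampling, matching
    the across-replicate spirit of triplicate ± SD reporting).
    """
    conc = iso.protein_concentrations
    resp = iso.normalized_responses
    if weights is None and iso.replicate_sd is not None and np.any(iso.replicate_sd > 0):
        weights = iso.replicate_sd
    kd, kd_se, residual_norm = _fit_log_kd(conc, resp, weights)
    if se_method == "bootstrap":
        kd_se = _bootstrap_kd_se(conc, resp, weights, n_boot, seed)
    elif se_method != "curvature":
        raise InvalidInputError(f"unknown se_method {se_method!r}")
    return KdEstimate(
        kd=kd, kd_se=kd_se, unit=iso.concentration_unit,
        n_points=int(conc.size), residual_norm=residual_norm,
        surface_id=iso.surface_id,
    )


def fit_anisotropy_kd(
    tit: AnisotropyTitration,
    se_method: str = "curvature",
    n_boot: int = 1000,
    seed: int = 0,
) -> KdEstimate:
    """Fit A_norm = 1/(1 + Kd/P0) to a normalised anisotropy titration.

    Anisotropy is first normalised via (A - A_min)/(A_max - A_min) using
    the supplied extremes or the observed min/max. Because the observed
    maximum underestimates the true saturation anisotropy whenever the
    titration does not fully plateau, the hyperbola is fit with a free
    saturation amplitude (profiled out in closed form); with a fully
    saturated titration the amplitude is 1 and the model reduces to
    A_norm = 1/(1 + Kd/P0). Valid in the ligand-excess regime
    P0 >> Pep0 where the bound-peptide fraction equals the
    site-occupancy hyperbola; a warning is attached to the result when
    that condition looks violated.
    """
    a_span = (tit.a_max if tit.a_max is not None else tit.anisotropy.max()) - (
        tit.a_min if tit.a_min is not None else tit.anisotropy.min()
    )
    noise_floor = 1e-4
    if not a_span > noise_floor:
        raise FitError("flat titration: anisotropy span is below the noise floor")
    warn: tuple[str, ...] = ()
    if not tit.ligand_excess_ok():
        msg = (
            "ligand-excess condition Pep0 << P0 appears violated; the "
            "fitted Kd may be biased upward"
        )
        warnings.warn(msg, stacklevel=2)
        warn = (msg,)
    resp = tit.normalized()
    kd, kd_se, residual_norm = _fit_log_kd(
        tit.protein_concentrations, resp, None, free_amplitude=True
    )
    if se_method == "bootstrap":
        kd_se = _bootstrap_kd_se(tit.protein_concentrations, resp, None, n_boot, seed)
    return KdEstimate(
        kd=kd, kd_se=kd_se, unit="uM", n_points=int(resp.size),
        residual_norm=residual_norm, surface_id=tit.peptide_id, warnings=warn,
    )


# ---------------------------------------------------------------------------
# Affinity comparisons
# ---------------------------------------------------------------------------

def _kd_and_unit(x) -> tuple[float, str | None]:
    if isinstance(x, KdEstimate):
        return x.kd, x.unit
    return float(x), None


def affinity_fold_change(kd_a, kd_b, mode: str = "kd_ratio") -> float:
    """Compare two dissociation constants.

    ``kd_ratio`` returns ``kd_a / kd_b`` (how many-fold tighter the second
    binding is: e.g. 560/100 = 5.6-fold increase in membrane affinity).
    ``affinity_percent`` returns ``100 * (kd_a/kd_b - 1)`` with ``kd_a``
    the weaker-affinity (larger-Kd) reference, i.e. the percent increase
    in affinity (affinity ~ 1/Kd) of b over a.

    Accepts floats (assumed same unit) or :class:`KdEstimate` objects,
    whose units must match.
    """
    a, unit_a = _kd_and_unit(kd_a)
    b, unit_b = _kd_and_unit(kd_b)
    if unit_a is not None and unit_b is not None and unit_a != unit_b:
        raise InvalidInputError(f"unit mismatch: {unit_a!r} vs {unit_b!r}")
    if not (a > 0 and b > 0):
        raise InvalidInputError("both Kd values must be positive")
    if mode == "kd_ratio":
        return a / b
    if mode == "affinity_percent":
        return 100.0 * (a / b - 1.0)
    raise InvalidInputError(f"unknown mode {mode!r}")


def selectivity_report(
    estimates: pd.DataFrame,
    reference_variant: str = "WT",
    reference_surface: str | None = None,
    selectivity_threshold: float = 2.0,
) -> pd.DataFrame:
    """Fold-change report from a table of fitted Kd values.

    Parameters
    ----------
    estimates:
        DataFrame with columns ``variant``, ``surface``, ``kd`` (one row
        per variant/surface pair; ``unit`` optional).
    reference_variant:
        Baseline variant (default ``"WT"``); must be present for every
        surface.
    reference_surface:
        When given, per-variant fold changes between each surface and this
        one are also emitted (e.g. the PI(3)P-vesicle surface).
    selectivity_threshold:
        Rows whose surface fold change versus the reference surface falls
        below this are flagged ``selectivity_lost``.

    Returns a tidy DataFrame with columns ``variant``, ``surface``,
    ``kd``, ``fold_vs_reference_variant`` (Kd variant / Kd reference on
    the same surface), ``fold_vs_reference_surface`` (Kd on reference
    surface / Kd on this surface, same variant; NaN when unavailable) and
    ``selectivity_lost``.
    """
    required = {"variant", "surface", "kd"}
    if not required.issubset(estimates.columns):
        raise InvalidInputError(f"estimates table needs columns {sorted(required)}")
    df = estimates.copy()
    ref_rows = df[df["variant"] == reference_variant].set_index("surface")["kd"]
    out = []
    for _, row in df.iterrows():
        if row["surface"] not in ref_rows.index:
            raise InvalidInputError(
                f"no {reference_variant} reference for surface {row['surface']!r}"
            )
        fold_vs_wt = row["kd"] / ref_rows[row["surface"]]
        fold_vs_surface = np.nan
        if reference_surface is not None:
            mine = df[(df["variant"] == row["variant"]) & (df["surface"] == reference_surface)]
            if len(mine) == 1 and np.isfinite(mine["kd"].iloc[0]):
                fold_vs_surface = mine["kd"].iloc[0] / row["kd"]
        out.append(
            {
                "variant": row["variant"],
                "surface": row["surface"],
                "kd": row["kd"],
                "fold_vs_reference_variant": fold_vs_wt,
                "fold_vs_reference_surface": fold_vs_surface,
                "selectivity_lost": bool(
                    np.isfinite(fold_vs_surface) and fold_vs_surface < selectivity_threshold
                ),
            }
        )
    return pd.DataFrame(out)


def pip2_dose_response(
    mole_percent: Sequence[float], responses: Sequence[float]
) -> dict:
    """Monotonicity verdict and slope for binding versus lipid dose.

    Duplicate mole-percent levels are averaged. Returns a dict with keys
    ``slope`` (least-squares, response per mol%), ``rank_correlation``
    (Spearman) and ``verdict`` (``"dose-dependent"`` when the rank
    correlation is exactly +1, ``"flat"`` when the responses are
    constant, otherwise ``"non-monotone"``).
    """
    x = np.asarray(mole_percent, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("mole_percent and responses must have equal length")
    df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False)["y"].mean()
    if len(df) < 3:
        raise InvalidInputError("need at least 3 distinct mole-percent levels")
    xs, ys = df["x"].to_numpy(), df["y"].to_numpy()
    slope = float(np.polyfit(xs, ys, 1)[0])
    if np.allclose(ys, ys[0]):
        return {"slope": slope, "rank_correlation": 0.0, "verdict": "flat"}
    rho = float(stats.spearmanr(xs, ys).statistic)
    verdict = "dose-dependent" if rho == 1.0 else "non-monotone"
    return {"slope": slope, "rank_correlation": rho, "verdict": verdict}


def load_reference_kd_table() -> pd.DataFrame:
    """Published Smad2 Kd reference table bundled with the package.

    Columns: ``variant``, ``surface``, ``kd``, ``sd``, ``unit`` (nM for
    vesicle surfaces, uM for receptor-derived peptides). ``NaN`` marks
    values not determined.
    """
    with resources.files("memquant.data").joinpath("smad2_kd_table.csv").open() as fh:
        return pd.read_csv(fh)
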