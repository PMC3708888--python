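"""Two-layer component-contribution estimator.

The reactant-contribution (RC) layer fits per-compound formation energies to
the measured reaction Gibbs energies by least squares; it is accurate but
only reaches queries inside the span of measured reactions.  The
group-contribution (GC) layer regresses the same observations on net group
changes, trading accuracy for coverage.  The component-contribution
estimator splits a query x into its component inside range(S) (scored by RC)
and the orthogonal remainder (scored by GC):

    ΔG°_cc(x) = xᵀ [ P_R (Sᵀ)⁺ + P_N G Λ⁺ ] b,      Λ = SᵀG

with P_R/P_N the projectors onto range(S) and null(Sᵀ) in compound space.
Because the estimate is a single linear functional of x, any set of
reactions summing to a null net reaction gets energies summing to exactly
zero — first-law consistency holds structurally, not approximately.

Uncertainty propagates through the same linear map: layer covariances are
the standard least-squares forms σ̂²·M⁺M⁺ᵀ, and queries whose group-space
remainder leaves the training span pick up a term α²·P_N G P_{N(Λ)} Gᵀ P_N
with a very large α, flagging them as uncovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import ReactionVector, TrainingData
from .groups import GroupIncidence
from .linalg import null_space_projector, projectors, pseudoinverse

__all__ = [
    "CCConfig",
    "TrainedModel",
    "EstimateWithUncertainty",
    "FitDiagnostics",
    "fit_rc",
    "fit_gc",
    "train",
    "estimate",
    "confidence_interval",
    "prediction_interval",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CCConfig:
    """Estimator settings.

    alpha_inf
        Stand-in for the infinite standard error assigned to uncovered
        reactions (kJ/mol); large enough to dominate any chemical energy.
    coverage_tol
        Relative threshold on the group-space remainder norm below which a
        query counts as covered.
    rel_tol
        Rank cutoff passed to the pseudoinverse (None → spectral default).
    squared_fraction_weights
        Whether the prediction-variance mixing weights are the squared-norm
        fractions ‖P_R x‖²/‖x‖² (exactly additive via Pythagoras) or the
        plain norm fractions.
    """

    alpha_inf: float = 1e10
    coverage_tol: float = 1e-10
    rel_tol: float | None = None
    squared_fraction_weights: bool = True
    use_weights: bool = False


@dataclass
class FitDiagnostics:
    residuals_rc: np.ndarray
    residuals_gc: np.ndarray
    dof_rc: int
    dof_gc: int
    rank_S: int
    rank_L: int


@dataclass
class EstimateWithUncertainty:
    """Point estimate with propagated uncertainty for one reaction."""

    dG0: float
    standard_error: float
    covered: bool
    rc_fraction: float

    def __iter__(self):
        yield from (self.dG0, self.standard_error, self.covered, self.rc_fraction)


@dataclass
class TrainedModel:
    """Everything needed to score any query reaction without retraining.

    ``w`` is the contribution vector (ΔG°_cc(x) = xᵀw) and ``V`` the finite
    part of the uncertainty matrix, so that for covered reactions
    SE²(x) = xᵀVx.  The infinite-uncertainty term for reactions leaving the
    group-space training span is kept in factored form: its contribution is
    α²·‖P_{N(Λ)} Gᵀ P_N x‖², evaluated as a norm rather than folded into a
    dense matrix (α² ≈ 1e20 would amplify epsilon-level projector residue
    into kJ/mol-scale garbage).  :meth:`uncertainty_matrix` assembles the
    full matrix including the α² term when the algebraic object itself is
    wanted.
    """

    compound_index: list[str]
    group_index: list[str]
    w: np.ndarray
    V: np.ndarray
    dGf_rc: np.ndarray
    dg_gc: np.ndarray
    P_R: np.ndarray
    P_N: np.ndarray
    G: np.ndarray
    P_null_L: np.ndarray  # group-space projector onto null(Λ)
    sigma2_rc: float
    sigma2_gc: float
    rank_S: int
    rank_L: int
    config: CCConfig = field(default_factory=CCConfig)
    diagnostics: FitDiagnostics | None = None

    @property
    def n_compounds(self) -> int:
        return len(self.compound_index)

    def uncertainty_matrix(self, include_alpha: bool = True) -> np.ndarray:
        """Full m×m matrix with SE²(x) = xᵀ·M·x (α² term optional)."""
        if not include_alpha:
            return self.V
        A = self.P_null_L @ self.G.T @ self.P_N
        return self.V + self.config.alpha_inf**2 * (A.T @ A)

    def group_remainder(self, xd: np.ndarray) -> np.ndarray:
        """Component of the query's group-space remainder outside range(Λᵀ)."""
        return self.P_null_L @ (self.G.T @ (self.P_N @ xd))


def _weighted(td: TrainingData, config: CCConfig) -> tuple[np.ndarray, np.ndarray]:
    """Optionally row-scale the system by sqrt(weights)."""
    A = td.S.T  # n × m design
    b = td.dG_obs
    if config.use_weights:
        sw = np.sqrt(td.weights)
        return A * sw[:, None], b * sw
    return A, b


def fit_rc(td: TrainingData, rel_tol: float | None = None):
    """Reactant-contribution least squares: formation energies from Sᵀf ≈ b.

    Returns ``(dGf_rc, fitted, residuals)`` where ``fitted`` is the
    orthogonal projection of the observations onto range(Sᵀ).
    """
    St = td.S.T
    St_pinv, _ = pseudoinverse(St, rel_tol)
    dGf = St_pinv @ td.dG_obs
    fitted = St @ dGf
    residuals = td.dG_obs - fitted
    return dGf, fitted, residuals


def fit_gc(td: TrainingData, gi: GroupIncidence, rel_tol: float | None = None):
    """Group-contribution least squares on Λ = SᵀG: Λ·Δg ≈ b.

    Group contributions take the minimal-norm solution, so groups never
    changed by any training reaction get contribution 0.
    """
    L = td.S.T @ gi.G
    L_pinv, _ = pseudoinverse(L, rel_tol)
    dg = L_pinv @ td.dG_obs
    residuals = td.dG_obs - L @ dg
    return dg, residuals


def train(td: TrainingData, gi: GroupIncidence, config: CCConfig | None = None) -> TrainedModel:
    """Fit both layers and assemble the component-contribution estimator.

    The residual sums of squares include any variance removed upstream by
    projecting the observations onto the first-law-consistent subspace
    (``td.projected_ss``): projection changes neither fit, only the
    bookkeeping of where the error shows up.

    Raises
    ------
    ValueError
        If either layer has no residual degrees of freedom
        (n_unique ≤ rank), so its error variance cannot be estimated.
    """
    config = config or CCConfig()
    if gi.compound_index != td.compound_index:
        raise ValueError("group incidence index must match training compound index")
    rel_tol = config.rel_tol
    S = td.S
    G = gi.G
    n = td.n_reactions
    St, b = _weighted(td, config)

    St_pinv, rank_S = pseudoinverse(St, rel_tol)
    pp = projectors(S, rel_tol)  # compound-space projectors onto range(S)/null(Sᵀ)
    L = St @ G
    L_pinv, rank_L = pseudoinverse(L, rel_tol)
    P_null_L, _ = null_space_projector(L, rel_tol)

    dGf_rc = St_pinv @ b
    fitted_rc = St @ dGf_rc
    res_rc = b - fitted_rc
    dg_gc = L_pinv @ b
    res_gc = b - L @ dg_gc

    dof_rc = n - rank_S
    dof_gc = n - rank_L
    if dof_rc <= 0:
        raise ValueError(
            f"no residual degrees of freedom for the RC layer (n={n}, rank(S)={rank_S}); "
            "add measured reactions or fix the error variance externally"
        )
    if dof_gc <= 0:
        raise ValueError(
            f"no residual degrees of freedom for the GC layer (n={n}, rank(Λ)={rank_L})"
        )
    rss_rc = float(res_rc @ res_rc) + td.projected_ss
    rss_gc = float(res_gc @ res_gc) + td.projected_ss
    sigma2_rc = rss_rc / dof_rc
    sigma2_gc = rss_gc / dof_gc

    Sigma_rc = sigma2_rc * (St_pinv @ St_pinv.T)
    Sigma_gc = sigma2_gc * (L_pinv @ L_pinv.T)

    P_R, P_N = pp.P_range, pp.P_null
    w = P_R @ (St_pinv @ b) + P_N @ (G @ (L_pinv @ b))
    V = P_R @ Sigma_rc @ P_R + P_N @ G @ Sigma_gc @ G.T @ P_N
    V = 0.5 * (V + V.T)

    diagnostics = FitDiagnostics(
        residuals_rc=res_rc,
        residuals_gc=res_gc,
        dof_rc=dof_rc,
        dof_gc=dof_gc,
        rank_S=rank_S,
        rank_L=rank_L,
    )
    return TrainedModel(
        compound_index=list(td.compound_index),
        group_index=list(gi.group_index),
        w=w,
        V=V,
        dGf_rc=dGf_rc,
        dg_gc=dg_gc,
        P_R=P_R,
        P_N=P_N,
        G=G.copy(),
        P_null_L=P_null_L,
        sigma2_rc=sigma2_rc,
        sigma2_gc=sigma2_gc,
        rank_S=rank_S,
        rank_L=rank_L,
        config=config,
        diagnostics=diagnostics,
    )


def _dense_query(model: TrainedModel, x: ReactionVector) -> tuple[np.ndarray, list[tuple[str, float]]]:
    known = np.zeros(model.n_compounds)
    pos = {c: i for i, c in enumerate(model.compound_index)}
    unknown: list[tuple[str, float]] = []
    for cid, coeff in x.coefficients:
        if cid in pos:
            known[pos[cid]] = coeff
        else:
            unknown.append((cid, coeff))
    return known, unknown


def estimate(model: TrainedModel, x: ReactionVector) -> EstimateWithUncertainty:
    """Score one reaction: point estimate, SE, coverage flag, RC fraction.

    Unknown compounds never raise: they yield ``covered=False`` with the
    infinite-uncertainty SE, so batch scoring of genome-scale models
    proceeds.  A null net reaction scores 0 ± 0.
    """
    if x.is_empty():
        return EstimateWithUncertainty(0.0, 0.0, True, 0.0)
    xd, unknown = _dense_query(model, x)
    norm2 = float(xd @ xd) + sum(c**2 for _, c in unknown)
    if norm2 == 0.0:
        return EstimateWithUncertainty(0.0, 0.0, True, 0.0)
    dG0 = float(xd @ model.w)
    se2 = float(xd @ model.V @ xd)
    x_R = model.P_R @ xd
    rc_fraction = float(x_R @ x_R) / norm2
    rem_norm = float(np.linalg.norm(model.group_remainder(xd)))
    covered = (not unknown) and (
        rem_norm <= model.config.coverage_tol * float(np.sqrt(norm2))
    )
    if unknown:
        se = model.config.alpha_inf
    elif covered:
        # below the coverage tolerance the remainder is numerical residue;
        # including its alpha^2 term would inject noise into a finite SE
        se = float(np.sqrt(max(se2, 0.0)))
    else:
        se = float(np.sqrt(max(se2, 0.0) + (model.config.alpha_inf * rem_norm) ** 2))
    return EstimateWithUncertainty(dG0, se, covered, rc_fraction)


def confidence_interval(est: EstimateWithUncertainty, level: float) -> tuple[float, float]:
    """Two-sided normal confidence interval dG0 ± z_{(1+γ)/2}·SE."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return est.dG0 - z * est.standard_error, est.dG0 + z * est.standard_error


def prediction_variance(model: TrainedModel, x: ReactionVector) -> float:
    """Mixed residual variance σ̂²_cc(x) for a new observation of x.

    A weighted mean of the two layers' error variances, weighted by the
    fractions of x lying in range(S) and null(Sᵀ) (squared-norm fractions by
    default, which sum to one exactly).
    """
    if x.is_empty():
        return 0.0
    xd, unknown = _dense_query(model, x)
    norm = float(np.linalg.norm(xd))
    if norm == 0.0 or unknown:
        return float("inf") if unknown else 0.0
    f_r = float(np.linalg.norm(model.P_R @ xd)) / norm
    f_n = float(np.linalg.norm(model.P_N @ xd)) / norm
    if model.config.squared_fraction_weights:
        w_r, w_n = f_r**2, f_n**2
    else:
        s = f_r + f_n
        w_r, w_n = f_r / s, f_n / s
    return w_r * model.sigma2_rc + w_n * model.sigma2_gc


def prediction_interval(model: TrainedModel, x: ReactionVector, level: float) -> tuple[float, float]:
    """Interval expected to contain a *new measurement* of reaction x.

    Combines the estimator's standard error with the mixed residual variance:
    dG0 ± z·√(σ̂²_cc(x) + SE²).  Uncovered reactions get an infinite-width
    interval.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    est = estimate(model, x)
    if not est.covered:
        return float("-inf"), float("inf")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * float(np.sqrt(prediction_variance(model, x) + est.standard_error**2))
    return est.dG0 - half, est.dG0 + half


# --- serialization ----------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(path, model: TrainedModel, header: dict | None = None) -> None:
    """Serialize a trained model to a single JSON file.

    Arrays are stored as nested lists; fine at desk scale and portable.
    """
    payload = {
        "format_version": _FORMAT_VERSION,
        "header": header or {},
        "compound_index": model.compound_index,
        "group_index": model.group_index,
        "w": model.w.tolist(),
        "V": model.V.tolist(),
        "dGf_rc": model.dGf_rc.tolist(),
        "dg_gc": model.dg_gc.tolist(),
        "P_R": model.P_R.tolist(),
        "P_N": model.P_N.tolist(),
        "G": model.G.tolist(),
        "P_null_L": model.P_null_L.tolist(),
        "sigma2_rc": model.sigma2_rc,
        "sigma2_gc": model.sigma2_gc,
        "rank_S": model.rank_S,
        "rank_L": model.rank_L,
        "config": {
            "alpha_inf": model.config.alpha_inf,
            "coverage_tol": model.config.coverage_tol,
            "rel_tol": model.config.rel_tol,
            "squared_fraction_weights": model.config.squared_fraction_weights,
            "use_weights": model.config.use_weights,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    cfg = CCConfig(**payload["config"])
    return TrainedModel(
        compound_index=list(payload["compound_index"]),
        group_index=list(payload["group_index"]),
        w=np.asarray(payload["w"], dtype=float),
        V=np.asarray(payload["V"], dtype=float),
        dGf_rc=np.asarray(payload["dGf_rc"], dtype=float),
        dg_gc=np.asarray(payload["dg_gc"], dtype=float),
        P_R=np.asarray(payload["P_R"], dtype=float),
        P_N=np.asarray(payload["P_N"], dtype=float),
        G=np.asarray(payload["G"], dtype=float),
        P_null_L=np.asarray(payload["P_null_L"], dtype=float),
        sigma2_rc=float(payload["sigma2_rc"]),
        sigma2_gc=float(payload["sigma2_gc"]),
        rank_S=int(payload["rank_S"]),
        rank_L=int(payload["rank_L"]),
        config=cfg,
    )
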