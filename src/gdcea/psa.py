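"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: costs are sampled from
normal distributions truncated at zero, utilities and transition
probabilities from beta distributions, each parameterised by method of
moments from its mean and a standard error of 10% of the mean.  Each draw
re-runs the full two-arm model; draws are summarised on the
cost-effectiveness plane and as a cost-effectiveness acceptability curve
(CEAC) over a willingness-to-pay grid.

Sampling order within a draw is fixed (imiglucerase price, ambroxol price,
live-state utilities in state order, monotherapy transition entries in
listed order, then combination entries), and shared parameters (prices,
utilities) take identical values in both arms — common random numbers for
a paired comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cea import EconomicResult, run_base_case
from .gd_model import LIVE_STATES, STATE_DEATH, GDParameters
from .owsa import utility_param

logger = logging.getLogger(__name__)


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters for a given mean and SE.

    ``alpha = mean·(mean(1−mean)/se² − 1)``, ``beta = (1−mean)·(same)``.

    Raises
    ------
    ValueError
        If ``mean`` is outside (0, 1) or the variance is infeasible
        (``se² >= mean(1−mean)``).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError("beta SE must be positive")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta variance: se²={se*se:.6g} >= mean(1-mean)="
            f"{mean * (1 - mean):.6g}"
        )
    k = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * k, (1.0 - mean) * k


def sample_beta(rng: np.random.Generator, mean: float, se: float) -> float:
    """One beta draw with the requested mean and SE (degenerate at se = 0)."""
    if se == 0.0:
        return mean
    a, b = beta_from_mean_se(mean, se)
    return float(rng.beta(a, b))


def sample_truncated_normal(
    rng: np.random.Generator, mean: float, se: float, max_redraws: int = 1000
) -> float:
    """One Normal(mean, se) draw truncated at 0 by rejection.

    Rejection (rather than clamping) preserves the distribution shape above
    zero.  Costs with a 10% coefficient of variation essentially never hit
    the bound, so the expected number of redraws is ~0.
    """
    if se < 0:
        raise ValueError("SE must be >= 0")
    if se == 0.0:
        return mean
    for _ in range(max_redraws):
        x = rng.normal(mean, se)
        if x >= 0.0:
            return float(x)
    raise RuntimeError(
        f"truncated-normal sampling failed after {max_redraws} redraws "
        f"(mean={mean}, se={se})"
    )


@dataclass(frozen=True)
class PSAConfig:
    """Monte-Carlo settings; SE defaults to 10% of each parameter's mean."""

    n_draws: int = 1000
    seed: int = 0
    se_fraction: float = 0.10
    sample_costs: bool = True
    sample_utilities: bool = True
    sample_transitions: bool = True
    wtp_points: int = 21
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.se_fraction < 0:
            raise ValueError("se_fraction must be >= 0")


def sample_parameter_set(
    params: GDParameters,
    config: PSAConfig,
    rng: np.random.Generator,
) -> GDParameters:
    """Draw one full parameter set around the base-case means.

    After sampling a row's transition probabilities, the diagonal is
    re-closed; a row whose sampled off-diagonal mass exceeds 1 is redrawn
    (bounded by ``config.max_redraws``).
    """
    from dataclasses import replace

    out = params.copy()
    f = config.se_fraction
    if config.sample_costs:
        out.imiglucerase = replace(
            out.imiglucerase,
            pack_price=sample_truncated_normal(
                rng, params.imiglucerase.pack_price, f * params.imiglucerase.pack_price,
                config.max_redraws,
            ),
        )
        out.ambroxol = replace(
            out.ambroxol,
            pack_price=sample_truncated_normal(
                rng, params.ambroxol.pack_price, f * params.ambroxol.pack_price,
                config.max_redraws,
            ),
        )
    if config.sample_utilities:
        for s in LIVE_STATES:
            mean = params.utilities[s]
            try:
                out.utilities[s] = sample_beta(rng, mean, f * mean)
            except ValueError as err:
                raise ValueError(f"{utility_param(s)}: {err}") from err
        out.utilities[STATE_DEATH] = 0.0
    if config.sample_transitions:
        for arm_key in ("mono", "combo"):
            out.transition_entries[arm_key] = _sample_transition_entries(
                params.transition_entries[arm_key], f, rng, config.max_redraws, arm_key
            )
    return out


def _sample_transition_entries(entries, f, rng, max_redraws, arm_key):
    rows: dict[str, list[tuple[int, str, float]]] = {}
    for i, (frm, to, p) in enumerate(entries):
        rows.setdefault(frm, []).append((i, to, p))
    sampled = list(entries)
    for frm, row in rows.items():
        for attempt in range(max_redraws):
            draws = [
                (i, to, sample_beta(rng, p, f * p) if p > 0 else p)
                for i, to, p in row
            ]
            if sum(d[2] for d in draws) <= 1.0:
                break
            logger.warning("redrawing over-full transition row %s/%s", arm_key, frm)
        else:
            raise RuntimeError(
                f"transition row {arm_key}/{frm} infeasible after {max_redraws} redraws"
            )
        for i, to, p in draws:
            sampled[i] = (frm, to, p)
    return sampled


def run_psa(
    params: GDParameters,
    config: PSAConfig | None = None,
    rng: np.random.Generator | None = None,
    half_cycle: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo PSA: one full two-arm model evaluation per draw.

    Returns a DataFrame with columns ``draw, cost_mono, qalys_mono,
    cost_combo, qalys_combo, incr_cost, incr_qalys``; reproducible given
    ``config.seed`` (or an explicit ``rng``).
    """
    config = config or PSAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    for d in range(config.n_draws):
        sampled = sample_parameter_set(params, config, rng)
        res = run_base_case(sampled, half_cycle=half_cycle)
        records.append(
            (d, res.cost_mono, res.qalys_mono, res.cost_combo, res.qalys_combo,
             res.incr_cost, res.incr_qalys)
        )
    return pd.DataFrame(
        records,
        columns=[
            "draw", "cost_mono", "qalys_mono", "cost_combo", "qalys_combo",
            "incr_cost", "incr_qalys",
        ],
    )


def ceac(draws: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Probability the combination arm is cost-effective at each WTP.

    A draw counts as cost-effective when its incremental net monetary
    benefit is strictly positive: ``wtp × ΔQALY − Δcost > 0``.
    """
    if len(draws) == 0:
        raise ValueError("CEAC requires at least one draw")
    wtp = np.asarray(wtp_grid, dtype=float)
    de = draws["incr_qalys"].to_numpy()
    dc = draws["incr_cost"].to_numpy()
    nmb = wtp[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp, "prob_combo_ce": prob})


@dataclass(frozen=True)
class CEPlaneSummary:
    """Quadrant counts and a 95% confidence ellipse on the CE plane.

    Quadrants classify draws by the sign of (ΔQALY, Δcost): NE = more
    effective and more costly, SE = more effective and cheaper, etc.
    The ellipse comes from the sample mean and covariance at the
    chi-square(2 df) quantile; it is ``None`` when the covariance is
    degenerate.
    """

    n_draws: int
    quadrants: dict[str, int]
    mean_incr_cost: float
    mean_incr_qalys: float
    ellipse_center: tuple[float, float] | None
    ellipse_axes: tuple[float, float] | None  # semi-axis lengths
    ellipse_angle_deg: float | None  # orientation of the major axis


def ce_plane_summary(draws: pd.DataFrame, confidence: float = 0.95) -> CEPlaneSummary:
    """Summarise PSA draws on the cost-effectiveness plane."""
    if len(draws) < 3:
        raise ValueError("CE-plane summary requires at least 3 draws")
    de = draws["incr_qalys"].to_numpy()
    dc = draws["incr_cost"].to_numpy()
    quadrants = {
        "NE": int(np.sum((de > 0) & (dc > 0))),
        "NW": int(np.sum((de <= 0) & (dc > 0))),
        "SE": int(np.sum((de > 0) & (dc <= 0))),
        "SW": int(np.sum((de <= 0) & (dc <= 0))),
    }
    xy = np.column_stack([de, dc])
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0) or not np.all(np.isfinite(evals)):
        logger.warning("degenerate CE-plane covariance; ellipse omitted")
        return CEPlaneSummary(
            n_draws=len(draws), quadrants=quadrants,
            mean_incr_cost=float(center[1]), mean_incr_qalys=float(center[0]),
            ellipse_center=None, ellipse_axes=None, ellipse_angle_deg=None,
        )
    q = stats.chi2.ppf(confidence, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    axes = tuple(float(np.sqrt(q * v)) for v in evals)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return CEPlaneSummary(
        n_draws=len(draws), quadrants=quadrants,
        mean_incr_cost=float(center[1]), mean_incr_qalys=float(center[0]),
        ellipse_center=(float(center[0]), float(center[1])),
        ellipse_axes=axes, ellipse_angle_deg=angle,
    )
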