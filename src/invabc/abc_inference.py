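"""ABC scenario choice, parameter estimation, confidence assessment and model
checking from a reference table of simulated summary statistics.

The pipeline is the classic rejection + regression construction: simulate
datasets under each scenario's prior, retain the simulations closest to the
observed summary vector (Euclidean distance on MAD-normalized, mask-aware
statistics), estimate scenario posterior probabilities by multinomial
logistic regression of the scenario label on the centred statistics evaluated
at the observed point, and adjust retained parameter draws by local-linear
regression with Epanechnikov weights.  Scenario-choice confidence (type I/II
error) is estimated end-to-end from pseudo-observed datasets (PODs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .abc_summaries import SummaryStatVector, summary_statistics
from .coalescent_engine import SimOptions, simulate_dataset
from .genotype_io import LocusDef
from .scenario_model import Scenario

logger = logging.getLogger(__name__)


# -- reference table ----------------------------------------------------------


@dataclass
class ReferenceTable:
    scenario_ids: np.ndarray  # (N,) int index into scenario_labels
    scenario_labels: list[str]
    param_names: list[str]
    params: np.ndarray  # (N, P)
    stat_names: list[str]
    stats: np.ndarray  # (N, S)
    mask: np.ndarray  # (N, S) True = defined
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def normalization(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-stat median and MAD over the table (MAD 0 flags a dead stat)."""
        med = np.median(self.stats, axis=0)
        mad = np.median(np.abs(self.stats - med), axis=0)
        return med, mad

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=self.stat_names)
        for i, p in enumerate(self.param_names):
            df.insert(i, p, self.params[:, i])
        df.insert(0, "scenario", [self.scenario_labels[i] for i in self.scenario_ids])
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _simulate_row(scenario: Scenario, panel, groups, options, rng) -> tuple[dict, SummaryStatVector]:
    draws = scenario.sample_priors(rng)
    g, aln = simulate_dataset(scenario, draws, panel, seed=rng, options=options)
    return draws, summary_statistics(g, aln, groups)


def build_reference_table(
    scenarios: list[Scenario],
    n_per_scenario: int,
    panel: list[LocusDef],
    seed: int = 0,
    options: SimOptions = SimOptions(),
    groups: list[str] | None = None,
    max_failures: int = 100,
    workers: int = 1,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows per scenario (uniform scenario prior).

    Rows are reproducible per (seed, scenario index, row index) regardless of
    ``workers``; simulation failures are logged and resampled.
    """
    labels = [s.id for s in scenarios]

    def one_row(s_idx: int, scenario: Scenario, groups_s: list[str], i: int):
        for attempt in range(max_failures):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s_idx, i, attempt]))
            try:
                draws, vec = _simulate_row(scenario, panel, groups_s, options, rng)
                return draws, vec, attempt
            except Exception as exc:  # noqa: BLE001 - resample failed rows
                logger.warning("simulation failed (scenario %s row %d): %s", scenario.id, i, exc)
        raise RuntimeError(f"too many simulation failures for scenario {scenario.id}")

    jobs = []
    for s_idx, scenario in enumerate(scenarios):
        groups_s = groups or [lab for _, _, _, lab in scenario.bound_samples()]
        jobs += [(s_idx, scenario, groups_s, i) for i in range(n_per_scenario)]
    if workers > 1:
        from joblib import Parallel, delayed

        produced = Parallel(n_jobs=workers)(delayed(one_row)(*job) for job in jobs)
    else:
        produced = [one_row(*job) for job in jobs]

    rows_stats, rows_mask, rows_params, rows_sid = [], [], [], []
    stat_names: list[str] | None = None
    param_names: list[str] | None = None
    n_failed = 0
    for (s_idx, _, _, _), (draws, vec, attempts) in zip(jobs, produced):
        n_failed += attempts
        if stat_names is None:
            stat_names = vec.names
        elif vec.names != stat_names:
            raise ValueError("inconsistent summary-statistic names across rows")
        if param_names is None:
            param_names = sorted(draws)
        rows_stats.append(vec.values)
        rows_mask.append(vec.mask)
        rows_params.append([draws.get(p, np.nan) for p in param_names])
        rows_sid.append(s_idx)
    return ReferenceTable(
        scenario_ids=np.array(rows_sid),
        scenario_labels=labels,
        param_names=list(param_names or []),
        params=np.array(rows_params),
        stat_names=list(stat_names or []),
        stats=np.vstack(rows_stats),
        mask=np.vstack(rows_mask),
        provenance={"seed": seed, "n_per_scenario": n_per_scenario, "n_resampled": n_failed},
    )


# -- rejection ----------------------------------------------------------------


@dataclass
class Retained:
    indices: np.ndarray  # row indices into the reference table, sorted by distance
    distances: np.ndarray
    stats_centered: np.ndarray  # normalized stats minus normalized observed
    scenario_ids: np.ndarray
    used_stats: np.ndarray  # boolean over stat columns


def rejection_sample(rt: ReferenceTable, observed: SummaryStatVector, tolerance: float = 0.01) -> Retained:
    """Retain the closest ceil(tolerance x N) rows to the observed vector.

    Distance is Euclidean over MAD-normalized statistics; columns that are
    masked-undefined in the observed vector, dead in the table (MAD = 0), or
    undefined in any row are excluded from the metric.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    if observed.names != rt.stat_names:
        raise ValueError("observed statistics do not match the reference table")
    med, mad = rt.normalization()
    usable = (mad > 0) & observed.mask & rt.mask.all(axis=0)
    z = (rt.stats[:, usable] - med[usable]) / mad[usable]
    z_obs = (observed.values[usable] - med[usable]) / mad[usable]
    centered = z - z_obs
    dist = np.sqrt(np.sum(centered**2, axis=1))
    n_keep = int(np.ceil(tolerance * rt.n_rows))
    if n_keep < 10:
        logger.warning("retaining only %d rows; posterior estimates will be noisy", n_keep)
    order = np.argsort(dist, kind="stable")[:n_keep]
    return Retained(
        indices=order,
        distances=dist[order],
        stats_centered=centered[order],
        scenario_ids=rt.scenario_ids[order],
        used_stats=usable,
    )


# -- scenario choice ----------------------------------------------------------


@dataclass
class ScenarioPosterior:
    table: pd.DataFrame  # scenario, posterior, ci_low, ci_high
    chosen: str
    n_retained: int
    method: str  # "logistic" or "rejection"

    def probability(self, scenario_id: str) -> float:
        row = self.table.loc[self.table["scenario"] == scenario_id, "posterior"]
        return float(row.iloc[0]) if len(row) else 0.0


def _rejection_posterior(retained: Retained, labels: list[str]) -> ScenarioPosterior:
    n = retained.scenario_ids.size
    rows = []
    for s_idx, lab in enumerate(labels):
        p = float(np.mean(retained.scenario_ids == s_idx))
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        rows.append({"scenario": lab, "posterior": p,
                     "ci_low": max(0.0, p - 1.96 * se), "ci_high": min(1.0, p + 1.96 * se)})
    tab = pd.DataFrame(rows)
    return ScenarioPosterior(tab, tab.loc[tab["posterior"].idxmax(), "scenario"], n, "rejection")


def _mnlogit_intercept_cov(X: np.ndarray, probs_rows: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the multinomial-logit intercepts.

    Observed-information inverse for the baseline-category parameterization
    (classes 1..K-1 vs class 0), intercept block extracted.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    k1 = probs_rows.shape[1] - 1
    dim = k1 * (p + 1)
    H = np.zeros((dim, dim))
    for j in range(k1):
        for m in range(k1):
            pj = probs_rows[:, j + 1]
            pm = probs_rows[:, m + 1]
            w = pj * ((1.0 if j == m else 0.0) - pm)
            block = (A * w[:, None]).T @ A
            H[j * (p + 1) : (j + 1) * (p + 1), m * (p + 1) : (m + 1) * (p + 1)] = block
    H += 1e-8 * np.eye(dim)
    cov = np.linalg.inv(H)
    pos = [j * (p + 1) for j in range(k1)]
    return cov[np.ix_(pos, pos)]


def logistic_scenario_posterior(
    retained: Retained,
    labels: list[str],
    max_features: int = 20,
    compute_ci: bool = True,
) -> ScenarioPosterior:
    """Multinomial logistic regression of scenario label on centred stats,
    evaluated at the observed point, with delta-method 95% CIs.

    The fit uses a weak ridge on the slope coefficients (intercepts
    unpenalized) to stay defined under near-separation; on a failed fit the
    estimate falls back to rejection proportions with multinomial CIs.
    Scenarios absent from the retained set get posterior 0.
    """
    present = np.unique(retained.scenario_ids)
    if present.size < 2:
        tab = pd.DataFrame(
            [
                {"scenario": lab, "posterior": 1.0 if s_idx in present else 0.0,
                 "ci_low": np.nan, "ci_high": np.nan}
                for s_idx, lab in enumerate(labels)
            ]
        )
        return ScenarioPosterior(tab, labels[int(present[0])], retained.scenario_ids.size, "degenerate")

    X = retained.stats_centered
    # guard dimensionality: project onto leading PCs when stats are many
    if X.shape[1] > max_features:
        X = PCA(n_components=max_features, random_state=0).fit_transform(X)
    sd = X.std(axis=0)
    X = X[:, sd > 0] / sd[sd > 0]
    y = np.searchsorted(present, retained.scenario_ids)  # relabel 0..K-1

    try:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=10.0, max_iter=2000).fit(X, y)
        probs_at_obs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        if not np.all(np.isfinite(probs_at_obs)):
            raise RuntimeError("non-finite posterior probabilities")
        rows = []
        if compute_ci:
            probs_rows = clf.predict_proba(X)
            cov_eta = _mnlogit_intercept_cov(X, probs_rows)
            k1 = present.size - 1
            for s in range(present.size):
                grad = np.array(
                    [probs_at_obs[s] * ((1.0 if s == j + 1 else 0.0) - probs_at_obs[j + 1])
                     for j in range(k1)]
                )
                var = float(grad @ cov_eta @ grad)
                half = 1.96 * np.sqrt(max(var, 0.0))
                rows.append((probs_at_obs[s], max(0.0, probs_at_obs[s] - half),
                             min(1.0, probs_at_obs[s] + half)))
        else:
            rows = [(p, np.nan, np.nan) for p in probs_at_obs]
        method = "logistic"
    except Exception as exc:  # noqa: BLE001
        logger.warning("logistic posterior failed (%s); falling back to rejection proportions", exc)
        return _rejection_posterior(retained, labels)

    tab_rows = []
    for s_idx, lab in enumerate(labels):
        if s_idx in present:
            pos = int(np.searchsorted(present, s_idx))
            p, lo, hi = rows[pos]
        else:
            p, lo, hi = 0.0, 0.0, 0.0
        tab_rows.append({"scenario": lab, "posterior": p, "ci_low": lo, "ci_high": hi})
    tab = pd.DataFrame(tab_rows)
    return ScenarioPosterior(
        tab, tab.loc[tab["posterior"].idxmax(), "scenario"], retained.scenario_ids.size, method
    )


def scenario_choice(
    rt: ReferenceTable, observed: SummaryStatVector, tolerance: float = 0.01,
    compute_ci: bool = True,
) -> ScenarioPosterior:
    return logistic_scenario_posterior(
        rejection_sample(rt, observed, tolerance), rt.scenario_labels, compute_ci=compute_ci
    )


# -- parameter estimation -----------------------------------------------------


def local_linear_adjust(
    rt: ReferenceTable,
    retained: Retained,
    param_names: list[str] | None = None,
    transform: str = "log",
    scenario_id: str | None = None,
    ridge: float = 1e-8,
    max_features: int = 20,
) -> pd.DataFrame:
    """Beaumont local-linear regression adjustment of retained parameter draws.

    Parameters are regressed (after log/logit/none transform) on the centred
    normalized statistics with Epanechnikov weights by distance; adjusted
    draws are the fit at the observed point plus residuals, back-transformed.
    Returns one row per retained simulation of the chosen scenario.  When the
    statistic space is larger than ``max_features`` the regression runs on
    the leading principal components (a regression with ~as many regressors
    as rows would absorb the residuals and collapse the posterior).
    """
    if transform not in ("log", "logit", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    idx = retained.indices
    keep = np.ones(idx.size, dtype=bool)
    if scenario_id is not None:
        s_idx = rt.scenario_labels.index(scenario_id)
        keep = retained.scenario_ids == s_idx
    if keep.sum() < 50:
        raise ValueError(f"need >= 50 retained rows of the chosen scenario, have {int(keep.sum())}")
    rows = idx[keep]
    X = retained.stats_centered[keep]
    n_comp = min(max_features, X.shape[0] // 5)
    if X.shape[1] > n_comp:
        X = PCA(n_components=n_comp, random_state=0).fit_transform(X)
    d = retained.distances[keep]
    d_max = d.max() if d.max() > 0 else 1.0
    w = 1.0 - (d / d_max) ** 2
    w = np.maximum(w, 1e-6)
    param_names = rt.param_names if param_names is None else list(param_names)

    out = {}
    for pname in param_names:
        theta = rt.params[rows, rt.param_names.index(pname)]
        if transform == "log":
            if np.any(theta <= 0):
                raise ValueError(f"log transform needs positive values for {pname}")
            t = np.log(theta)
        elif transform == "logit":
            if np.any((theta <= 0) | (theta >= 1)):
                raise ValueError(f"logit transform needs values in (0,1) for {pname}")
            t = np.log(theta / (1 - theta))
        else:
            t = theta.astype(float)
        A = np.column_stack([np.ones(X.shape[0]), X])
        Aw = A * w[:, None]
        gram = A.T @ Aw + ridge * np.eye(A.shape[1])
        try:
            beta = np.linalg.solve(gram, Aw.T @ t)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(Aw, t * np.sqrt(w), rcond=None)[0]
            logger.warning("rank-deficient local-linear fit for %s; least-squares fallback", pname)
        fitted = A @ beta
        adjusted = beta[0] + (t - fitted)  # fit at observed point (X=0) + residuals
        if transform == "log":
            adjusted = np.exp(adjusted)
        elif transform == "logit":
            adjusted = 1.0 / (1.0 + np.exp(-adjusted))
        out[pname] = adjusted
    return pd.DataFrame(out)


def posterior_summary(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Median and 2.5/97.5% quantiles per parameter."""
    rows = []
    for pname in adjusted.columns:
        q = np.quantile(adjusted[pname], [0.5, 0.025, 0.975])
        rows.append({"parameter": pname, "median": q[0], "q2.5": q[1], "q97.5": q[2]})
    return pd.DataFrame(rows)


# -- confidence in scenario choice --------------------------------------------


def confidence_error_rates(
    rt: ReferenceTable,
    scenarios: list[Scenario],
    panel: list[LocusDef],
    n_pods: int = 20,
    seed: int = 0,
    tolerance: float = 0.01,
    options: SimOptions = SimOptions(),
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Type I/II scenario-choice error from PODs, run through the same
    rejection + logistic pipeline as the real analysis.

    type I for s: fraction of s-PODs where s is not chosen; type II for s:
    fraction of non-s PODs where s is chosen.
    """
    labels = rt.scenario_labels
    chosen = np.empty((len(scenarios), n_pods), dtype=np.int64)
    for s_idx, scenario in enumerate(scenarios):
        groups_s = groups or [lab for _, _, _, lab in scenario.bound_samples()]
        for p in range(n_pods):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 7000 + s_idx, p]))
            _, vec = _simulate_row(scenario, panel, groups_s, options, rng)
            post = scenario_choice(rt, vec, tolerance)
            chosen[s_idx, p] = labels.index(post.chosen)
    rows = []
    for s_idx, lab in enumerate(labels):
        type1 = float(np.mean(chosen[s_idx] != s_idx))
        others = np.delete(chosen, s_idx, axis=0)
        type2 = float(np.mean(others == s_idx))
        rows.append({"scenario": lab, "type_I": type1, "type_II": type2, "n_pods": n_pods})
    return pd.DataFrame(rows)


# -- model checking -----------------------------------------------------------


def pca_model_check(
    rt: ReferenceTable,
    observed: SummaryStatVector,
    posterior_stats: np.ndarray | None = None,
    n_components: int = 3,
) -> dict:
    """PCA of normalized prior-simulation stats; the observed vector (and any
    posterior-predictive simulations) projected into that space.

    Reports per-PC percentiles of the observed point within the prior (and
    posterior) clouds plus variance explained.
    """
    med, mad = rt.normalization()
    usable = (mad > 0) & observed.mask
    z = (rt.stats[:, usable] - med[usable]) / mad[usable]
    n_components = min(n_components, z.shape[1], z.shape[0])
    pca = PCA(n_components=n_components, random_state=0).fit(z)
    proj_prior = pca.transform(z)
    z_obs = ((observed.values[usable] - med[usable]) / mad[usable]).reshape(1, -1)
    proj_obs = pca.transform(z_obs)[0]
    report = {
        "variance_explained_pct": (100 * pca.explained_variance_ratio_).tolist(),
        "observed_projection": proj_obs.tolist(),
        "prior_percentile": [
            float(np.mean(proj_prior[:, c] <= proj_obs[c]) * 100) for c in range(n_components)
        ],
    }
    if posterior_stats is not None and len(posterior_stats):
        zp = (posterior_stats[:, usable] - med[usable]) / mad[usable]
        proj_post = pca.transform(zp)
        report["posterior_percentile"] = [
            float(np.mean(proj_post[:, c] <= proj_obs[c]) * 100) for c in range(n_components)
        ]
    return report
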