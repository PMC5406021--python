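"""Per-population diversity, pairwise differentiation with permutation tests,
and the Mantel test.

Estimators:

* F_ST: Weir & Cockerham's theta, ratio-of-sums over alleles and loci.
* Jost's D and G''_ST: Nei/Chesson-corrected HS and HT with the two-sample
  (k = 2) finite-sample factors; the multilocus value averages HS and HT across
  loci before forming ratios, with the per-locus-ratio mean available as an
  option.
* Phi_PT: AMOVA among-population variance fraction over squared codominant
  genotypic distances (half the squared Euclidean distance between per-locus
  allele-count vectors).

Negative estimates are reported raw; formatted reports may clip at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "diversity_summary",
    "pairwise_fst",
    "pairwise_jostD_gst",
    "pairwise_phipt",
    "pairwise_matrices",
    "permutation_test",
    "mantel_test",
]


# -- diversity ----------------------------------------------------------------


def _locus_stats(calls: np.ndarray) -> dict | None:
    """Diversity components for one population x locus from (n, 2) calls."""
    scored = calls[:, 0] != MISSING
    calls = calls[scored]
    n = calls.shape[0]
    if n == 0:
        return None
    alleles = calls.ravel()
    vals, counts = np.unique(alleles, return_counts=True)
    p = counts / (2 * n)
    he = 1.0 - float(np.sum(p**2))
    ho = float(np.mean(calls[:, 0] != calls[:, 1]))
    return {
        "N": n,
        "Na": len(vals),
        "Ne_eff": 1.0 / float(np.sum(p**2)),
        "Ho": ho,
        "He": he,
        "uHe": (2 * n / (2 * n - 1)) * he,
        "F": (1.0 - ho / he) if he > 0 else np.nan,
    }


def diversity_summary(g: GenotypeMatrix, exclude_imputed: bool = True) -> pd.DataFrame:
    """N, Na, Ne_eff, Ho, He, uHe, F per population x locus plus per-population
    means with standard errors across loci (rows with locus == "mean"/"se")."""
    rows = []
    pops = g.samples["population"].to_numpy()
    for pop in g.populations:
        idx = np.flatnonzero(pops == pop)
        per_locus = []
        for j, locus in enumerate(g.loci):
            calls = g.calls[idx, j, :].copy()
            if exclude_imputed:
                calls[g.imputed[idx, j]] = MISSING
            st = _locus_stats(calls)
            if st is None:
                continue
            per_locus.append(st)
            rows.append({"population": pop, "locus": locus.name, **st})
        if per_locus:
            df = pd.DataFrame(per_locus)
            rows.append({"population": pop, "locus": "mean", **df.mean().to_dict()})
            se = (df.std(ddof=1) / np.sqrt(len(df))).to_dict()
            rows.append({"population": pop, "locus": "se", **se})
    return pd.DataFrame(rows)


# -- Weir-Cockerham theta -----------------------------------------------------


def _wc_locus_components(calls_by_pop: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) variance components for one locus over r populations.

    Each element of ``calls_by_pop`` is an (n_i, 2) array of scored calls.
    """
    r = len(calls_by_pop)
    ns = np.array([c.shape[0] for c in calls_by_pop], dtype=float)
    if np.any(ns < 1) or r < 2:
        return 0.0, 0.0, 0.0
    alleles = np.unique(np.concatenate([c.ravel() for c in calls_by_pop]))
    n_al = alleles.size
    # per-population allele frequencies and heterozygote frequencies, vectorized
    p_mat = np.empty((r, n_al))
    h_mat = np.empty((r, n_al))
    for i, c in enumerate(calls_by_pop):
        idx0 = np.searchsorted(alleles, c[:, 0])
        idx1 = np.searchsorted(alleles, c[:, 1])
        freq = np.bincount(idx0, minlength=n_al) + np.bincount(idx1, minlength=n_al)
        p_mat[i] = freq / (2.0 * c.shape[0])
        het = idx0 != idx1
        h = np.bincount(idx0[het], minlength=n_al) + np.bincount(idx1[het], minlength=n_al)
        h_mat[i] = h / c.shape[0]
    nbar = ns.mean()
    n_tot = ns.sum()
    nc = (n_tot - (ns**2).sum() / n_tot) / (r - 1)
    pbar = (ns[:, None] * p_mat).sum(axis=0) / n_tot
    s2 = (ns[:, None] * (p_mat - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ns[:, None] * h_mat).sum(axis=0) / n_tot
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) * hbar / (4 * nbar)
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _pop_calls(g: GenotypeMatrix, pop: str, j: int, exclude_imputed: bool) -> np.ndarray:
    idx = g.population_rows(pop)
    calls = g.calls[idx, j, :].copy()
    if exclude_imputed:
        calls[g.imputed[idx, j]] = MISSING
    return calls[calls[:, 0] != MISSING]


def pairwise_fst(g: GenotypeMatrix, popA: str, popB: str, exclude_imputed: bool = True) -> float:
    """Multilocus Weir-Cockerham theta between two populations (ratio of sums)."""
    num = den = 0.0
    shared = 0
    for j in range(g.n_loci):
        ca = _pop_calls(g, popA, j, exclude_imputed)
        cb = _pop_calls(g, popB, j, exclude_imputed)
        if ca.shape[0] < 1 or cb.shape[0] < 1:
            continue
        shared += 1
        a, b, c = _wc_locus_components([ca, cb])
        num += a
        den += a + b + c
    if shared == 0:
        raise ValueError(f"no shared scored loci between {popA} and {popB}")
    return num / den if den != 0 else 0.0


# -- Jost's D and G''_ST ------------------------------------------------------


def _hs_ht_locus(ca: np.ndarray, cb: np.ndarray) -> tuple[float, float] | None:
    """Nei & Chesson unbiased HS/HT estimates for one locus, two samples."""
    na, nb = ca.shape[0], cb.shape[0]
    if na < 1 or nb < 1:
        return None
    k = 2
    alleles = np.unique(np.concatenate([ca.ravel(), cb.ravel()]))
    pa = np.array([np.mean(ca == al) for al in alleles])
    pb = np.array([np.mean(cb == al) for al in alleles])
    hs_obs = 1.0 - (np.sum(pa**2) + np.sum(pb**2)) / 2
    pm = (pa + pb) / 2
    ht_obs = 1.0 - float(np.sum(pm**2))
    n_harm = k / (1.0 / na + 1.0 / nb)
    hs = (2 * n_harm / (2 * n_harm - 1)) * hs_obs
    ht = ht_obs + hs / (2 * n_harm * k)
    return hs, ht


def pairwise_jostD_gst(
    g: GenotypeMatrix,
    popA: str,
    popB: str,
    exclude_imputed: bool = True,
    multilocus: str = "mean_components",
) -> tuple[float, float]:
    """(Jost's D, G''_ST) between two populations.

    ``multilocus="mean_components"`` averages HS and HT over loci before the
    ratio (recommended); ``"mean_ratios"`` averages per-locus ratios.
    """
    k = 2
    hs_list, ht_list = [], []
    for j in range(g.n_loci):
        ca = _pop_calls(g, popA, j, exclude_imputed)
        cb = _pop_calls(g, popB, j, exclude_imputed)
        est = _hs_ht_locus(ca, cb)
        if est is not None:
            hs_list.append(est[0])
            ht_list.append(est[1])
    if not hs_list:
        raise ValueError(f"no shared scored loci between {popA} and {popB}")

    def _ratios(hs: float, ht: float) -> tuple[float, float]:
        if hs >= 1.0:
            return np.nan, np.nan
        d = (k / (k - 1)) * (ht - hs) / (1 - hs)
        gpp = k * (ht - hs) / ((k * ht - hs) * (1 - hs)) if (k * ht - hs) != 0 else 0.0
        return d, gpp

    if multilocus == "mean_components":
        return _ratios(float(np.mean(hs_list)), float(np.mean(ht_list)))
    pairs = [_ratios(hs, ht) for hs, ht in zip(hs_list, ht_list)]
    return tuple(np.nanmean(np.array(pairs), axis=0))  # type: ignore[return-value]


# -- Phi_PT (AMOVA) -----------------------------------------------------------


def _genotypic_distance_sq(g: GenotypeMatrix, rows: np.ndarray, exclude_imputed: bool) -> np.ndarray:
    """Pairwise squared codominant genotypic distances between individuals.

    Per locus, half the squared Euclidean distance between allele-count
    vectors; loci missing in either individual are skipped for that pair.
    """
    n = len(rows)
    d2 = np.zeros((n, n))
    for j in range(g.n_loci):
        calls = g.calls[rows, j, :].copy()
        if exclude_imputed:
            calls[g.imputed[rows, j]] = MISSING
        scored = calls[:, 0] != MISSING
        alleles = np.unique(calls[scored].ravel())
        if alleles.size == 0:
            continue
        counts = np.zeros((n, alleles.size))
        for a_idx, al in enumerate(alleles):
            counts[:, a_idx] = (calls == al).sum(axis=1)
        diff = counts[:, None, :] - counts[None, :, :]
        contrib = 0.5 * np.sum(diff**2, axis=2)
        pair_ok = scored[:, None] & scored[None, :]
        d2 += np.where(pair_ok, contrib, 0.0)
    return d2


def pairwise_phipt(g: GenotypeMatrix, popA: str, popB: str, exclude_imputed: bool = True) -> float:
    """AMOVA-based Phi_PT: among-population fraction of molecular variance."""
    return phipt_from_rows(
        g,
        [g.population_rows(popA), g.population_rows(popB)],
        exclude_imputed=exclude_imputed,
    )


def phipt_from_rows(g: GenotypeMatrix, groups: list[np.ndarray], exclude_imputed: bool = True) -> float:
    rows = np.concatenate(groups)
    sizes = [len(gr) for gr in groups]
    if min(sizes) < 2:
        raise ValueError("each population needs >= 2 individuals for AMOVA")
    d2 = _genotypic_distance_sq(g, rows, exclude_imputed)
    N, K = len(rows), len(groups)
    iu = np.triu_indices(N, 1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    start = 0
    for sz in sizes:
        block = d2[start : start + sz, start : start + sz]
        ss_within += block[np.triu_indices(sz, 1)].sum() / sz
        start += sz
    ss_among = ss_total - ss_within
    df_among, df_within = K - 1, N - K
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (N - sum(sz**2 for sz in sizes) / N) / (K - 1)
    var_among = (ms_among - ms_within) / n0
    denom = var_among + ms_within
    return float(var_among / denom) if denom != 0 else 0.0


# -- permutation significance -------------------------------------------------


def permutation_test(
    stat_fn,
    g: GenotypeMatrix,
    popA: str,
    popB: str,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Permute individuals between two populations; one-tailed upper p-value.

    Returns ``(observed, p)`` with ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sub = g.for_populations([popA, popB])
    obs = stat_fn(sub, popA, popB)
    labels = sub.samples["population"].to_numpy().copy()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm = GenotypeMatrix(
            sub.samples.assign(population=labels), sub.loci, sub.calls, sub.imputed
        )
        if stat_fn(perm, popA, popB) >= obs - 1e-12:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


def pairwise_matrices(
    g: GenotypeMatrix,
    stats: tuple[str, ...] = ("fst", "gst", "jostd", "phipt"),
    n_perm: int = 0,
    seed: int | None = 0,
    exclude_imputed: bool = True,
) -> dict[str, pd.DataFrame]:
    """Symmetric pairwise matrices (and p-value matrices when n_perm > 0)."""
    pops = g.populations
    fns = {
        "fst": lambda s, a, b: pairwise_fst(s, a, b, exclude_imputed),
        "jostd": lambda s, a, b: pairwise_jostD_gst(s, a, b, exclude_imputed)[0],
        "gst": lambda s, a, b: pairwise_jostD_gst(s, a, b, exclude_imputed)[1],
        "phipt": lambda s, a, b: pairwise_phipt(s, a, b, exclude_imputed),
    }
    out: dict[str, pd.DataFrame] = {}
    for name in stats:
        mat = pd.DataFrame(0.0, index=pops, columns=pops)
        pmat = pd.DataFrame(np.nan, index=pops, columns=pops)
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                if n_perm > 0:
                    val, p = permutation_test(fns[name], g, a, b, n_perm, seed)
                    pmat.loc[a, b] = pmat.loc[b, a] = p
                else:
                    val = fns[name](g, a, b)
                mat.loc[a, b] = mat.loc[b, a] = val
        out[name] = mat
        if n_perm > 0:
            out[f"{name}_p"] = pmat
    return out


# -- Mantel test --------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    r_squared: float
    slope: float
    intercept: float
    p: float
    n_perm: int


def mantel_test(
    genetic: np.ndarray,
    geographic: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> MantelResult:
    """Mantel correlation between two square symmetric distance matrices.

    Pearson r over lower-triangle entries; the regression line is genetic on
    geographic; p from joint row/column permutations of the genetic matrix
    (one-tailed, upper).
    """
    gen = np.asarray(genetic, dtype=float)
    geo = np.asarray(geographic, dtype=float)
    if gen.shape != geo.shape or gen.ndim != 2 or gen.shape[0] != gen.shape[1]:
        raise ValueError("matrices must be square and of matching shape")
    n = gen.shape[0]
    il = np.tril_indices(n, -1)
    x, y = geo[il], gen[il]
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = gen[np.ix_(perm, perm)][il]
        if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs,
        r_squared=r_obs**2,
        slope=float(slope),
        intercept=float(intercept),
        p=(1 + count) / (n_perm + 1),
        n_perm=n_perm,
    )


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km (coordinates in degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * 6371.0088 * np.arcsin(np.sqrt(a)))
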