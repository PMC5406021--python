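"""Summary-statistic vectors for ABC, computed identically on observed and
simulated datasets.

Default menu (per sample group, then per group pair):

* microsatellites — mean allele count, mean unbiased genic diversity, mean
  allele-size variance (repeat units), mean M index; pairwise Weir-Cockerham
  F_ST, shared-allele distance DAS, and (delta mu)^2;
* sequence locus — haplotype count, segregating sites S, mean pairwise
  differences, Tajima's D; pairwise mean between-sample differences and
  Hudson's F_ST.

Statistics undefined on a dataset (e.g. Tajima's D at S = 0) are imputed 0
with a mask bit recorded; rejection distances are mask-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .mtdna_stats import SequenceAlignment, _pairwise_diffs, segregating_sites
from .popgen_stats import _wc_locus_components

_SECTION_ORDER = {"msat_one": 0, "msat_pair": 1, "seq_one": 2, "seq_pair": 3, "": 9}


@dataclass
class SummaryStatVector:
    names: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]  # True = defined
    section: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.size, dtype=bool)
        if not (len(self.names) == self.values.size == self.mask.size):
            raise ValueError("names, values and mask lengths differ")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def assemble_vector(parts: list[SummaryStatVector]) -> SummaryStatVector:
    """Concatenate partial vectors in canonical section order (input order of
    parts does not matter)."""
    if not parts:
        raise ValueError("no parts to assemble")
    ordered = sorted(parts, key=lambda p: (_SECTION_ORDER.get(p.section, 9), p.names[0]))
    return SummaryStatVector(
        names=[n for p in ordered for n in p.names],
        values=np.concatenate([p.values for p in ordered]),
        mask=np.concatenate([p.mask for p in ordered]),
    )


# -- microsatellite statistics -----------------------------------------------


def _group_rows(g: GenotypeMatrix, groups: list[str] | None) -> dict[str, np.ndarray]:
    groups = g.populations if groups is None else list(groups)
    pops = g.samples["population"].to_numpy()
    out = {}
    for grp in groups:
        rows = np.flatnonzero(pops == grp)
        if rows.size == 0:
            raise ValueError(f"empty sample group {grp!r}")
        out[grp] = rows
    return out


def _shared_allele_distance(ca: np.ndarray, cb: np.ndarray) -> float:
    """DAS = 1 - mean proportion of shared alleles across cross-sample pairs.

    ``ca``/``cb`` are (n, L, 2) call arrays; missing calls are skipped pairwise.
    """
    a1, a2 = ca[:, None, :, 0], ca[:, None, :, 1]
    b1, b2 = cb[None, :, :, 0], cb[None, :, :, 1]
    m11, m12 = a1 == b1, a1 == b2
    m21, m22 = a2 == b1, a2 == b2
    eq_multiset = (m11 & m22) | (m12 & m21)
    any_common = m11 | m12 | m21 | m22
    shared = np.where(eq_multiset, 2, np.where(any_common, 1, 0)).astype(float)
    ok = (a1 != MISSING) & (b1 != MISSING)
    with np.errstate(invalid="ignore"):
        prop = np.where(ok, shared / 2.0, np.nan)
    return 1.0 - float(np.nanmean(prop))


def microsat_stats(g: GenotypeMatrix, groups: list[str] | None = None,
                   pairs: bool = True) -> list[SummaryStatVector]:
    """One-sample and two-sample microsatellite summary partials."""
    rows_by = _group_rows(g, groups)
    motifs = np.array([loc.motif_length for loc in g.loci], dtype=float)
    # repeat-unit anchor: global per-locus minimum over the whole dataset
    mins = np.empty(g.n_loci)
    for j in range(g.n_loci):
        scored = g.calls[:, j, :][g.calls[:, j, :] != MISSING]
        mins[j] = scored.min() if scored.size else 0.0

    one_names, one_vals, one_mask = [], [], []
    per_group_units: dict[str, list[np.ndarray]] = {}
    for grp, rows in rows_by.items():
        ks, hes, variances, ms = [], [], [], []
        units_by_locus = []
        for j in range(g.n_loci):
            alleles = g.calls[rows, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            units = (alleles - mins[j]) / motifs[j]
            units_by_locus.append(units)
            n = alleles.size
            if n < 2:
                continue
            vals, counts = np.unique(alleles, return_counts=True)
            p = counts / n
            ks.append(len(vals))
            hes.append((n / (n - 1)) * (1.0 - float(np.sum(p**2))))
            variances.append(float(np.var(units, ddof=1)))
            r = units.max() - units.min()
            ms.append(len(vals) / (r + 1.0))
        per_group_units[grp] = units_by_locus
        for stat, arr in (("NAL", ks), ("HET", hes), ("VAR", variances), ("MGW", ms)):
            one_names.append(f"{stat}_{grp}")
            defined = len(arr) > 0
            one_vals.append(float(np.mean(arr)) if defined else 0.0)
            one_mask.append(defined)
    parts = [SummaryStatVector(one_names, np.array(one_vals), np.array(one_mask), "msat_one")]

    if pairs and len(rows_by) > 1:
        names, vals, mask = [], [], []
        grps = list(rows_by)
        for i, ga in enumerate(grps):
            for gb in grps[i + 1 :]:
                ra, rb = rows_by[ga], rows_by[gb]
                num = den = 0.0
                dmu = []
                for j in range(g.n_loci):
                    ca = g.calls[ra, j, :]
                    cb = g.calls[rb, j, :]
                    ca = ca[ca[:, 0] != MISSING]
                    cb = cb[cb[:, 0] != MISSING]
                    if len(ca) < 1 or len(cb) < 1:
                        continue
                    a, b, c = _wc_locus_components([ca, cb])
                    num += a
                    den += a + b + c
                    ua, ub = per_group_units[ga][j], per_group_units[gb][j]
                    if ua.size and ub.size:
                        dmu.append((ua.mean() - ub.mean()) ** 2)
                fst = num / den if den != 0 else 0.0
                das = _shared_allele_distance(g.calls[ra], g.calls[rb])
                for stat, val, ok in (
                    ("FST", fst, den != 0),
                    ("DAS", das, np.isfinite(das)),
                    ("DM2", float(np.mean(dmu)) if dmu else 0.0, bool(dmu)),
                ):
                    names.append(f"{stat}_{ga}_{gb}")
                    vals.append(val if ok else 0.0)
                    mask.append(ok)
        parts.append(SummaryStatVector(names, np.array(vals), np.array(mask), "msat_pair"))
    return parts


# -- sequence statistics ------------------------------------------------------


def _tajima_from_pi(n: int, S: int, k_hat: float) -> float:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((k_hat - S / a1) / np.sqrt(var))


def sequence_stats(aln: SequenceAlignment, groups: list[str] | None = None,
                   pairs: bool = True) -> list[SummaryStatVector]:
    """One-sample and two-sample sequence summary partials."""
    groups = sorted(set(aln.samples["population"])) if groups is None else list(groups)
    pops = aln.samples["population"].to_numpy()
    rows_by = {}
    for grp in groups:
        rows = np.flatnonzero(pops == grp)
        if rows.size == 0:
            raise ValueError(f"empty sample group {grp!r}")
        rows_by[grp] = rows

    names, vals, mask = [], [], []
    within_pi: dict[str, float] = {}
    for grp, rows in rows_by.items():
        seqs = aln.seqs[rows]
        n = len(rows)
        nhap = len(np.unique(seqs, axis=0))
        S = segregating_sites(seqs)
        diffs, _ = _pairwise_diffs(seqs)
        iu = np.triu_indices(n, 1)
        k_hat = float(np.mean(diffs[iu])) if n > 1 else 0.0
        within_pi[grp] = k_hat
        taj_ok = n >= 4 and S >= 1
        taj = _tajima_from_pi(n, S, k_hat) if taj_ok else 0.0
        for stat, val, ok in (
            ("NHA", nhap, True), ("SEG", S, True), ("PID", k_hat, n > 1), ("TAJ", taj, taj_ok),
        ):
            names.append(f"{stat}_{grp}")
            vals.append(float(val) if ok else 0.0)
            mask.append(ok)
    parts = [SummaryStatVector(names, np.array(vals), np.array(mask), "seq_one")]

    if pairs and len(rows_by) > 1:
        pnames, pvals, pmask = [], [], []
        grps = list(rows_by)
        for i, ga in enumerate(grps):
            for gb in grps[i + 1 :]:
                sa, sb = aln.seqs[rows_by[ga]], aln.seqs[rows_by[gb]]
                both = np.vstack([sa, sb])
                diffs, _ = _pairwise_diffs(both)
                between = float(np.mean(diffs[: len(sa), len(sa) :]))
                pw = 0.5 * (within_pi[ga] + within_pi[gb])
                fst_ok = between > 0
                fst = 1.0 - pw / between if fst_ok else 0.0
                pnames += [f"PIB_{ga}_{gb}", f"FSTS_{ga}_{gb}"]
                pvals += [between, fst]
                pmask += [True, fst_ok]
        parts.append(SummaryStatVector(pnames, np.array(pvals), np.array(pmask), "seq_pair"))
    return parts


def summary_statistics(
    g: GenotypeMatrix,
    aln: SequenceAlignment | None = None,
    groups: list[str] | None = None,
    pairs: bool = True,
) -> SummaryStatVector:
    """The full canonical summary vector for one dataset."""
    parts = microsat_stats(g, groups, pairs)
    if aln is not None:
        parts += sequence_stats(aln, groups, pairs)
    return assemble_vector(parts)
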