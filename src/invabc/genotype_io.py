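"""Reading, correction, filtering and imputation of microsatellite genotype tables.

The genotype file dialect is a long-header CSV/TSV modelled on GenAlEx exports:
one row per individual with columns ``id, population, year`` followed by two
allele-size columns per locus (``<locus>_1, <locus>_2``).  A ``0`` or an empty
cell means a missing allele; both alleles of a call are either present or
missing together.

Allele sizes are kept in base pairs internally.  Conversion to repeat units
happens only inside the operations that need it (M-ratio, stepwise-mutation
summaries), anchored at the per-locus minimum observed allele.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

VALID_DYES = ("VIC", "NED", "PET", "FAM")


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: name, repeat-unit length in bp, and dye label."""

    name: str
    motif_length: int
    dye: str = "FAM"

    def __post_init__(self) -> None:
        if self.motif_length not in (2, 3):
            raise ValueError(
                f"locus {self.name}: motif_length must be 2 or 3, got {self.motif_length}"
            )
        if self.dye not in VALID_DYES:
            raise ValueError(f"locus {self.name}: unknown dye {self.dye!r}")


def default_panel() -> list[LocusDef]:
    """The 13-locus panel shape used throughout: 2 dinucleotide + 11 trinucleotide."""
    dyes = VALID_DYES
    panel = [LocusDef(f"Di{i + 1}", 2, dyes[i % 4]) for i in range(2)]
    panel += [LocusDef(f"Tri{i + 1}", 3, dyes[(i + 2) % 4]) for i in range(11)]
    return panel


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls per individual x locus.

    ``calls`` is an ``(n_individuals, n_loci, 2)`` int array of allele sizes in
    bp with :data:`MISSING` for absent alleles; ``imputed`` flags calls filled
    in by :func:`impute_missing` so downstream statistics can exclude them.
    """

    samples: pd.DataFrame  # columns: id, population, year
    loci: list[LocusDef]
    calls: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.samples), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if self.imputed is None:
            self.imputed = np.zeros((n, L), dtype=bool)
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("half-missing calls: both alleles must be present or MISSING")
        if np.any((self.calls <= 0) & ~miss):
            raise ValueError("allele sizes must be positive integers")
        if self.samples["id"].duplicated().any():
            dup = self.samples["id"][self.samples["id"].duplicated()].tolist()
            raise ValueError(f"duplicate individual ids: {dup}")

    # -- basic views ----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def scored_loci_per_individual(self) -> np.ndarray:
        return (~self.missing_mask()).sum(axis=1)

    def subset(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples.iloc[rows],
            self.loci,
            self.calls[rows],
            self.imputed[rows],
        )

    def for_populations(self, pops) -> "GenotypeMatrix":
        keep = self.samples["population"].isin(list(pops)).to_numpy()
        return self.subset(np.flatnonzero(keep))

    def population_rows(self, population: str) -> np.ndarray:
        return np.flatnonzero((self.samples["population"] == population).to_numpy())


# -- I/O ----------------------------------------------------------------------


def read_genotype_table(path, panel: list[LocusDef], sep: str = ",") -> GenotypeMatrix:
    """Read a delimited genotype table into a :class:`GenotypeMatrix`.

    Expects a header ``id,population,year`` then two columns per locus.  Empty
    cells and ``0`` encode missing alleles.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    meta = df.iloc[:, :3].copy()
    meta.columns = ["id", "population", "year"]
    allele_cols = df.columns[3:]
    if len(allele_cols) != 2 * len(panel):
        raise ValueError(
            f"expected {2 * len(panel)} allele columns for a {len(panel)}-locus panel, "
            f"found {len(allele_cols)}"
        )
    raw = df[allele_cols].to_numpy()
    flat = np.empty(raw.shape, dtype=np.int64)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce")
        bad = col.notna() & (col != col.round())
        if bad.any():
            raise ValueError(f"non-integer allele size in column {allele_cols[j]!r}")
        flat[:, j] = col.fillna(0).astype(np.int64)
    calls = flat.reshape(len(df), len(panel), 2).astype(np.int32)
    # 0 / blank -> MISSING; a half-missing pair is promoted to fully missing.
    miss = calls <= 0
    pair_missing = miss.any(axis=2)
    calls[pair_missing] = MISSING
    g = GenotypeMatrix(meta, panel, calls)
    logger.info("read %d individuals x %d loci from %s", g.n_individuals, g.n_loci, path)
    return g


def write_genotype_table(g: GenotypeMatrix, path, sep: str = ",") -> None:
    """Write the inverse of :func:`read_genotype_table` (missing written as 0)."""
    out = g.samples.copy()
    for j, locus in enumerate(g.loci):
        for a in (0, 1):
            col = g.calls[:, j, a].copy()
            col[col == MISSING] = 0
            out[f"{locus.name}_{a + 1}"] = col
    out.to_csv(path, sep=sep, index=False)


# -- correction / filtering / imputation -------------------------------------


def apply_dye_shift(g: GenotypeMatrix, shifts: dict[str, int]) -> GenotypeMatrix:
    """Shift allele sizes by a per-locus dye offset (bp); MISSING unchanged.

    ``shifts`` maps locus name -> integer offset.  Loci not covered default to
    an offset of 0 with a logged warning.
    """
    calls = g.calls.copy()
    for j, locus in enumerate(g.loci):
        if locus.name not in shifts:
            logger.warning("no dye-shift offset for locus %s (dye %s); using 0", locus.name, locus.dye)
            continue
        off = int(shifts[locus.name])
        scored = calls[:, j, :] != MISSING
        calls[:, j, :][scored] += off
    return GenotypeMatrix(g.samples.copy(), g.loci, calls, g.imputed.copy())


def filter_min_loci(g: GenotypeMatrix, min_scored: int = 9) -> GenotypeMatrix:
    """Drop individuals scored at fewer than ``min_scored`` loci.

    The default of 9 (of 13) removes poor-quality samples while keeping
    partially genotyped individuals informative.
    """
    if min_scored > g.n_loci:
        raise ValueError(f"min_scored={min_scored} exceeds panel size {g.n_loci}")
    scored = g.scored_loci_per_individual()
    keep = scored >= min_scored
    removed = g.samples["id"][~keep].tolist()
    if removed:
        logger.info("filter_min_loci removed %d individuals: %s", len(removed), removed)
    return g.subset(np.flatnonzero(keep))


def allele_frequencies(g: GenotypeMatrix, exclude_imputed: bool = False):
    """Per population x locus allele frequencies over scored gene copies.

    Returns ``{(population, locus_name): ({allele: freq}, n_gene_copies)}``;
    frequencies sum to 1 per cell.
    """
    out: dict[tuple[str, str], tuple[dict[int, float], int]] = {}
    pops = g.samples["population"].to_numpy()
    for pop in g.populations:
        rows = np.flatnonzero(pops == pop)
        for j, locus in enumerate(g.loci):
            alleles = g.calls[rows, j, :].ravel()
            if exclude_imputed:
                ok = np.repeat(~g.imputed[rows, j], 2)
                alleles = alleles[ok]
            alleles = alleles[alleles != MISSING]
            n = alleles.size
            if n == 0:
                out[(pop, locus.name)] = ({}, 0)
                continue
            vals, counts = np.unique(alleles, return_counts=True)
            out[(pop, locus.name)] = (
                {int(v): c / n for v, c in zip(vals, counts)},
                int(n),
            )
    return out


def impute_missing(
    g: GenotypeMatrix, mode: str = "sampled", seed: int | None = 0
) -> GenotypeMatrix:
    """Replace missing calls from population allele frequencies.

    ``mode="sampled"`` draws each missing allele i.i.d. from its population's
    locus allele frequencies (deterministic under ``seed``); ``mode="expected"``
    substitutes the modal allele (ties broken by smallest size).  Imputation
    never crosses populations; a population x locus with zero scored calls is
    left missing and flagged in the returned matrix's log.
    """
    if mode not in ("sampled", "expected"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    rng = np.random.default_rng(seed)
    freqs = allele_frequencies(g)
    calls = g.calls.copy()
    imputed = g.imputed.copy()
    pops = g.samples["population"].to_numpy()
    unimputable: list[tuple[str, str]] = []
    for j, locus in enumerate(g.loci):
        miss_rows = np.flatnonzero(calls[:, j, 0] == MISSING)
        for i in miss_rows:
            table, n = freqs[(pops[i], locus.name)]
            if n == 0:
                if (pops[i], locus.name) not in unimputable:
                    unimputable.append((pops[i], locus.name))
                continue
            alleles = np.array(sorted(table))
            p = np.array([table[int(a)] for a in alleles])
            if mode == "sampled":
                calls[i, j, :] = rng.choice(alleles, size=2, p=p)
            else:
                calls[i, j, :] = alleles[np.argmax(p)]
            imputed[i, j] = True
    if unimputable:
        logger.warning("no data to impute %d population x locus cells: %s", len(unimputable), unimputable)
    return GenotypeMatrix(g.samples.copy(), g.loci, calls, imputed)


def qc_report(raw: GenotypeMatrix, filtered: GenotypeMatrix, imputed: GenotypeMatrix) -> dict:
    """Structured QC summary for the read -> filter -> impute pipeline."""
    removed = sorted(set(raw.samples["id"]) - set(filtered.samples["id"]))
    return {
        "n_input": raw.n_individuals,
        "n_retained": filtered.n_individuals,
        "removed_ids": removed,
        "n_imputed_calls": int(imputed.imputed.sum() - filtered.imputed.sum()),
        "n_loci": raw.n_loci,
    }


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


# -- repeat-unit conversion (used by M-ratio and stepwise summaries) ----------


def repeat_units(g: GenotypeMatrix, locus_index: int, rows: np.ndarray | None = None,
                 exclude_imputed: bool = False) -> np.ndarray:
    """Scored alleles at one locus converted to whole repeat units.

    Anchored at the minimum observed allele; raises if allele spacing is not a
    multiple of the locus motif length.
    """
    locus = g.loci[locus_index]
    calls = g.calls if rows is None else g.calls[rows]
    alleles = calls[:, locus_index, :].ravel()
    if exclude_imputed:
        imp = g.imputed if rows is None else g.imputed[rows]
        alleles = alleles[np.repeat(~imp[:, locus_index], 2)]
    alleles = alleles[alleles != MISSING]
    if alleles.size == 0:
        return alleles
    rel = alleles - alleles.min()
    if np.any(rel % locus.motif_length != 0):
        raise ValueError(
            f"locus {locus.name}: allele sizes not on a {locus.motif_length}-bp lattice"
        )
    return rel // locus.motif_length
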