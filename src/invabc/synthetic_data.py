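"""Study-like synthetic datasets with known truth, plus deterministic toy
fixtures with brute-force expected-statistic sidecars.

The study template emulates the shape of the real data the pipeline targets:
six regional sample groups (two with serial, multi-year samples), a 13-locus
microsatellite panel (2 dinucleotide + 11 trinucleotide), 20-30 diploid
individuals per sample, a small missing-call rate, and a 445-bp haploid
mtDNA locus.  What it does not emulate: genotyping error, null alleles and
allele binning artefacts, selection, or continuous migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent_engine import SimOptions, simulate_dataset
from .genotype_io import MISSING, GenotypeMatrix, LocusDef, default_panel
from .mtdna_stats import SequenceAlignment
from .scenario_model import Scenario, build_study_scenarios


@dataclass
class StudyTemplate:
    panel: list[LocusDef] = field(default_factory=default_panel)
    missing_rate: float = 0.03
    seq_length: int = 445
    options: SimOptions = field(default_factory=SimOptions)

    def __post_init__(self) -> None:
        self.options = SimOptions(
            seq_length=self.seq_length,
            ancestral_repeats=self.options.ancestral_repeats,
            size_offset_bp=self.options.size_offset_bp,
            mt_ne_scale=self.options.mt_ne_scale,
            p_gsm=self.options.p_gsm,
            rate_shape=self.options.rate_shape,
            simulate_sequence=self.options.simulate_sequence,
        )


def inject_missing(g: GenotypeMatrix, rate: float, rng: np.random.Generator) -> GenotypeMatrix:
    calls = g.calls.copy()
    drop = rng.random((g.n_individuals, g.n_loci)) < rate
    calls[drop] = MISSING
    return GenotypeMatrix(g.samples.copy(), g.loci, calls)


def generate_study_like(
    scenario: Scenario | None = None,
    truth: dict[str, float] | None = None,
    template: StudyTemplate | None = None,
    seed: int = 0,
):
    """One study-shaped dataset plus a truth ledger.

    Defaults to the shipped scenario 4.  ``truth`` may pin the full parameter
    vector; otherwise it is drawn from the scenario priors under ``seed``.
    Returns ``(GenotypeMatrix, SequenceAlignment, truth_record)``.
    """
    template = template or StudyTemplate()
    if scenario is None:
        scenario = next(s for s in build_study_scenarios() if s.id == "4")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    draws = dict(truth) if truth is not None else scenario.sample_priors(rng)
    g, aln = simulate_dataset(scenario, draws, template.panel, seed=rng, options=template.options)
    if template.missing_rate > 0:
        g = inject_missing(g, template.missing_rate, rng)
    record = {
        "scenario": scenario.id,
        "seed": seed,
        "missing_rate": template.missing_rate,
        "params": draws,
    }
    return g, aln, record


# -- deterministic toy fixtures ----------------------------------------------


def _matrix(pop_calls: dict[str, list[list[tuple[int, int]]]], loci: list[LocusDef]) -> GenotypeMatrix:
    ids, pops, rows = [], [], []
    for pop, individuals in pop_calls.items():
        for i, genotypes in enumerate(individuals):
            ids.append(f"{pop}_{i:02d}")
            pops.append(pop)
            rows.append([list(call) for call in genotypes])
    meta = pd.DataFrame({"id": ids, "population": pops, "year": 2015})
    return GenotypeMatrix(meta, loci, np.array(rows, dtype=np.int32))


def make_toy_fixtures() -> dict:
    """Small deterministic datasets with brute-force expected-value sidecars.

    * ``fixed_difference``: two populations fixed for different alleles at
      both loci (F_ST = DAS = 1 exactly).
    * ``smm_equilibrium``: a hand-written moderately diverse single
      population (all loci on the repeat lattice).
    * ``post_bottleneck``: gappy allele ranges typical of a crashed
      population (mean M-ratio below the 0.68 flag).
    * ``sequences``: six 20-bp haploid sequences in two populations with the
      pairwise-difference sidecar enumerated by hand below.
    """
    loci2 = [LocusDef("Di1", 2, "FAM"), LocusDef("Tri1", 3, "VIC")]

    fixed = _matrix(
        {
            "A": [[(100, 100), (150, 150)]] * 4,
            "B": [[(108, 108), (162, 162)]] * 4,
        },
        loci2,
    )

    smm = _matrix(
        {
            "P": [
                [(100, 102), (150, 153)],
                [(102, 104), (153, 153)],
                [(100, 104), (150, 156)],
                [(102, 102), (153, 156)],
                [(104, 106), (156, 159)],
                [(100, 106), (150, 159)],
            ]
        },
        loci2,
    )

    # alleles {0, 4, 5} and {0, 5} in repeat units: k/(r+1) = 3/6 and 2/6
    post = _matrix(
        {
            "P": [
                [(100, 108), (150, 165)],
                [(108, 110), (150, 150)],
                [(100, 110), (165, 165)],
                [(110, 110), (150, 165)],
            ]
        },
        loci2,
    )

    seqs = [
        ("s1", "X", "ACGTACGTACGTACGTACGT"),
        ("s2", "X", "ACGTACGTACGTACGTACGT"),
        ("s3", "X", "ACGTACGAACGTACGTACGT"),
        ("s4", "Y", "ACGTACGAACGAACGTACGT"),
        ("s5", "Y", "ACGTACGAACGAACGTACGA"),
        ("s6", "Y", "ACGTACGAACGAACGTACGA"),
    ]
    meta = pd.DataFrame(
        {"id": [s[0] for s in seqs], "population": [s[1] for s in seqs], "year": 2015}
    )
    aln = SequenceAlignment(
        meta, np.vstack([np.frombuffer(s[2].encode(), dtype=np.uint8) for s in seqs])
    )

    # brute-force sidecars, computed directly from the definitions
    seq_strings = [s[2] for s in seqs]
    n, L = len(seq_strings), len(seq_strings[0])
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(sum(a != b for a, b in zip(seq_strings[i], seq_strings[j])))
    pi_expected = (sum(diffs) / len(diffs)) / L
    hap_counts: dict[str, int] = {}
    for s in seq_strings:
        hap_counts[s] = hap_counts.get(s, 0) + 1
    hd_expected = (n / (n - 1)) * (1 - sum((c / n) ** 2 for c in hap_counts.values()))

    post_m_expected = (3 / 6 + 2 / 6) / 2  # enumerated allele lattices above

    return {
        "fixed_difference": {"matrix": fixed, "expected": {"fst": 1.0, "das": 1.0}},
        "smm_equilibrium": {"matrix": smm, "expected": {}},
        "post_bottleneck": {"matrix": post, "expected": {"mean_m": post_m_expected}},
        "sequences": {
            "alignment": aln,
            "expected": {"pi": pi_expected, "hd": hd_expected, "n_haplotypes": len(hap_counts)},
        },
    }
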