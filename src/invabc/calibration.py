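"""Study-condition calibration experiments.

Self-contained experiment definitions used to verify the pipeline end to end:
coalescent timing against the analytic expectation, scenario-choice recovery
on a three-scenario toy, split-time interval coverage on a two-population
toy, and type-I / power of the TPM heterozygosity-excess bottleneck test.
Each experiment returns plain dictionaries of measured quantities so callers
(tests, reproduction scripts) can assert or report them.
"""

from __future__ import annotations

import numpy as np

from .abc_inference import (
    build_reference_table,
    local_linear_adjust,
    rejection_sample,
    scenario_choice,
)
from .bottleneck_tests import TPMParams, heterozygosity_excess_test
from .coalescent_engine import SimOptions, simulate_dataset, simulate_gene_tree
from .genotype_io import LocusDef
from .scenario_model import (
    NeChangeEvent,
    PriorSpec,
    SampleEvent,
    Scenario,
    SplitEvent,
)

TOY_PANEL = [LocusDef(f"L{i + 1}", 3, "FAM") for i in range(5)]
STUDY_PANEL_SHAPE = [2, 2] + [3] * 11


def single_population_scenario(ne: float = 500.0, n_diploid: int = 1) -> Scenario:
    return Scenario(
        id="one", populations=["P"], root="P", events=[],
        samples=[SampleEvent("P", 2015, n_diploid)],
        params={"N_P": PriorSpec("fixed", ne)}, ne0={"P": "N_P"},
    )


def tmrca_calibration(ne: float = 500.0, reps: int = 2000, seed: int = 0,
                      ploidy: int = 1) -> dict:
    """Mean TMRCA of two gene copies vs the analytic expectation
    (Ne generations haploid, 2Ne diploid)."""
    n_dip = 1 if ploidy == 2 else 2
    sc = single_population_scenario(ne, n_diploid=n_dip)
    rng = np.random.default_rng(seed)
    tm = [
        simulate_gene_tree(sc, {"N_P": ne}, ploidy=ploidy, seed=rng).tmrca()
        for _ in range(reps)
    ]
    expected = ploidy * ne
    mean = float(np.mean(tm))
    return {
        "mean_tmrca": mean,
        "expected": expected,
        "relative_error": abs(mean - expected) / expected,
        "n_reps": reps,
    }


# -- three-scenario topology toy ---------------------------------------------


def _toy_priors() -> dict[str, PriorSpec]:
    # mutation floor keeps per-locus theta above ~0.1 so draws stay polymorphic
    # (a monomorphic 5-locus dataset carries no topology information)
    p = {f"N_{x}": PriorSpec("uniform", 100, 600) for x in "ABC"}
    p["t1"] = PriorSpec("uniform", 50, 150)
    p["t2"] = PriorSpec("uniform", 300, 600)
    p["mu_di"] = PriorSpec("loguniform", 3e-4, 1e-3)
    p["mu_tri"] = PriorSpec("loguniform", 3e-4, 1e-3)
    return p


def toy_three_scenarios(n_diploid: int = 10) -> list[Scenario]:
    """Three scenarios over populations {A, B, C} differing only in split
    order/topology: ((A,B),C), ((A,C),B) and the chain A->B->C."""
    samples = [SampleEvent(x, 2015, n_diploid) for x in "ABC"]
    topologies = {
        "AB_C": [SplitEvent("t1", "B", "A"), SplitEvent("t2", "C", "A")],
        "AC_B": [SplitEvent("t1", "C", "A"), SplitEvent("t2", "B", "A")],
        "chain": [SplitEvent("t1", "C", "B"), SplitEvent("t2", "B", "A")],
    }
    return [
        Scenario(
            id=sid, populations=list("ABC"), root="A", events=events,
            samples=list(samples), params=_toy_priors(),
            ne0={x: f"N_{x}" for x in "ABC"}, conditions=["t2 > t1"],
        )
        for sid, events in topologies.items()
    ]


def scenario_recovery_experiment(
    n_per_scenario: int = 20000,
    n_pods: int = 50,
    tolerance: float = 0.01,
    seed: int = 0,
) -> dict:
    """Fraction of PODs whose generating scenario attains the highest
    logistic posterior, on the three-scenario toy."""
    scenarios = toy_three_scenarios()
    options = SimOptions(simulate_sequence=False)
    rt = build_reference_table(scenarios, n_per_scenario, TOY_PANEL, seed=seed, options=options)
    groups = [lab for _, _, _, lab in scenarios[0].bound_samples()]
    wins = 0
    total = 0
    per_scenario: dict[str, int] = {s.id: 0 for s in scenarios}
    from .abc_inference import _simulate_row

    for s_idx, scenario in enumerate(scenarios):
        for p in range(n_pods // len(scenarios) + 1):
            if total >= n_pods:
                break
            rng = np.random.default_rng(np.random.SeedSequence([seed, 500 + s_idx, p]))
            _, vec = _simulate_row(scenario, TOY_PANEL, groups, options, rng)
            post = scenario_choice(rt, vec, tolerance)
            if post.chosen == scenario.id:
                wins += 1
                per_scenario[scenario.id] += 1
            total += 1
    return {
        "recovery_rate": wins / total,
        "n_pods": total,
        "n_per_scenario": n_per_scenario,
        "wins_per_scenario": per_scenario,
    }


# -- two-population split-time coverage ---------------------------------------


def toy_split_scenario(n_diploid: int = 10) -> Scenario:
    params = {
        "N_A": PriorSpec("uniform", 200, 1000),
        "N_B": PriorSpec("uniform", 200, 1000),
        "T": PriorSpec("uniform", 100, 1000),
        "mu_di": PriorSpec("loguniform", 3e-4, 1e-3),
        "mu_tri": PriorSpec("loguniform", 3e-4, 1e-3),
    }
    return Scenario(
        id="split", populations=["A", "B"], root="A",
        events=[SplitEvent("T", "B", "A")],
        samples=[SampleEvent(x, 2015, n_diploid) for x in "AB"],
        params=params, ne0={"A": "N_A", "B": "N_B"},
    )


def split_time_coverage_experiment(
    n_rows: int = 20000,
    n_pods: int = 40,
    tolerance: float = 0.02,
    seed: int = 0,
) -> dict:
    """95% credible-interval coverage for the split time T of a two-population
    toy, after local-linear adjustment."""
    scenario = toy_split_scenario()
    options = SimOptions(simulate_sequence=False)
    rt = build_reference_table([scenario], n_rows, TOY_PANEL, seed=seed, options=options)
    groups = [lab for _, _, _, lab in scenario.bound_samples()]
    from .abc_inference import _simulate_row

    hits = 0
    widths = []
    for p in range(n_pods):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 900, p]))
        truth, vec = _simulate_row(scenario, TOY_PANEL, groups, options, rng)
        retained = rejection_sample(rt, vec, tolerance)
        adj = local_linear_adjust(rt, retained, param_names=["T"], transform="log")
        lo, hi = np.quantile(adj["T"], [0.025, 0.975])
        if lo <= truth["T"] <= hi:
            hits += 1
        widths.append(hi - lo)
    return {
        "coverage": hits / n_pods,
        "n_pods": n_pods,
        "n_rows": n_rows,
        "mean_interval_width": float(np.mean(widths)),
    }


# -- bottleneck-test operating characteristics --------------------------------


def equilibrium_scenario(ne: float, mu: float, n_diploid: int = 30) -> Scenario:
    return Scenario(
        id="equilibrium", populations=["P"], root="P", events=[],
        samples=[SampleEvent("P", 2015, n_diploid)],
        params={
            "N_P": PriorSpec("fixed", ne),
            "mu_di": PriorSpec("fixed", mu),
            "mu_tri": PriorSpec("fixed", mu),
        },
        ne0={"P": "N_P"},
    )


def crash_scenario(
    t_crash: float = 8.0, ne_pre: float = 1000.0, ne_post: float = 10.0,
    mu: float = 2e-3, n_diploid: int = 30,
) -> Scenario:
    """A founder-type crash: Ne drops ``ne_pre/ne_post``-fold at ``t_crash``
    generations before sampling (defaults: 100x, 8 generations)."""
    return Scenario(
        id="crash", populations=["P"], root="P",
        events=[NeChangeEvent(t_crash, "P", ne_pre)],
        samples=[SampleEvent("P", 2015, n_diploid)],
        params={
            "N_P": PriorSpec("fixed", ne_post),
            "mu_di": PriorSpec("fixed", mu),
            "mu_tri": PriorSpec("fixed", mu),
        },
        ne0={"P": "N_P"},
    )


def study_shape_panel() -> list[LocusDef]:
    return [
        LocusDef(f"L{j + 1}", m, "FAM") for j, m in enumerate(STUDY_PANEL_SHAPE)
    ]


def _bottleneck_rejection_rate(
    scenario: Scenario, reps: int, seed: int, tpm: TPMParams, heq_iters: int, heq_seed: int
) -> dict:
    panel = study_shape_panel()
    options = SimOptions(simulate_sequence=False, p_gsm=0.9)
    label = scenario.samples[0].label()
    rejections = 0
    valid = 0
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        g, _ = simulate_dataset(scenario, scenario.sample_priors(rng), panel, seed=rng, options=options)
        out = heterozygosity_excess_test(g, label, tpm, iters=heq_iters, seed=heq_seed)
        if np.isfinite(out.wilcoxon_p):
            valid += 1
            if out.wilcoxon_p < 0.05:
                rejections += 1
    return {"rejection_rate": rejections / valid, "n_valid": valid, "n_reps": reps}


def bottleneck_type1_experiment(
    reps: int = 200, theta: float = 5.0, ne: float = 5000.0,
    seed: int = 1000, heq_iters: int = 1000, heq_seed: int = 42,
) -> dict:
    """Type-I rate of the TPM heterozygosity-excess test on mutation-drift
    equilibrium replicates (theta = 4 Ne mu per locus)."""
    mu = theta / (4.0 * ne)
    out = _bottleneck_rejection_rate(
        equilibrium_scenario(ne, mu), reps, seed, TPMParams(), heq_iters, heq_seed
    )
    out["nominal_alpha"] = 0.05
    return out


def bottleneck_power_experiment(
    reps: int = 200, seed: int = 5000, heq_iters: int = 1000, heq_seed: int = 42,
) -> dict:
    """Rejection rate of the same test on staged 100x founder crashes."""
    return _bottleneck_rejection_rate(
        crash_scenario(), reps, seed, TPMParams(), heq_iters, heq_seed
    )
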