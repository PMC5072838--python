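#!/usr/bin/env python
"""Simulate the 150-cycle serial-transfer experiment and detect its phases.

Runs the default configuration (11.5 h growth, 30 min capillary selection,
2048-fold bottleneck at a 1e5-cell census, one mutation event per cycle on
average, plasticity unlocked by 10% of mutations) and classifies the weekly
population summaries into the three adaptive phases.

Finding: the population first gains chemotaxis with no measurable growth
cost, then climbs the trade-off front to its constrained optimum and stalls,
and finally — once a plasticity mutation (low motility investment during
growth, high at selection time) reaches a majority — breaks through the
front, recovering growth rate while keeping chemotaxis.

Writes results/simulation_weekly.tsv, results/simulation_events.log and
results/simulation_phases.tsv.
"""

from pathlib import Path

from chemoscape.io import write_table
from chemoscape.simulator import detect_phases, run_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    OUT.mkdir(exist_ok=True)
    record = run_experiment(rng_seed=SEED)
    write_table(record.weekly, OUT / "simulation_weekly.tsv",
                provenance=f"04_evolution_simulation seed={SEED}",
                columns=("week", "cycle", "mean_r_diff", "mean_c_diff",
                         "mean_fitness", "plastic_fraction", "front_residual"))
    (OUT / "simulation_events.log").write_text(
        "\n".join(record.events) + "\n", encoding="utf-8"
    )

    phases = detect_phases(record)
    with open(OUT / "simulation_phases.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# generator: 04_evolution_simulation seed={SEED}\n")
        fh.write("phase\tdetected\tweeks\n")
        for name, ok, weeks in (
            ("cost_free_chemotaxis_gain", phases.phase1, phases.phase1_weeks),
            ("front_constrained_optimum", phases.phase2, phases.phase2_weeks),
            ("plasticity_breakthrough", phases.phase3, phases.phase3_weeks),
        ):
            fh.write(f"{name}\t{ok}\t{','.join(map(str, weeks))}\n")

    print(record.weekly.to_string(index=False,
                                  float_format=lambda v: f"{v:8.3f}"))
    print(f"\nfront: c = {record.front.intercept:.2f} "
          f"{record.front.slope:+.2f} r; optimum at "
          f"(r={record.optimum.r_opt:.3f}, c={record.optimum.c_opt:.2f})")
    print(f"phase 1 (cost-free chemotaxis gain): weeks {phases.phase1_weeks}")
    print(f"phase 2 (at the constrained optimum): weeks {phases.phase2_weeks}")
    print(f"phase 3 (breakthrough beyond front):  weeks {phases.phase3_weeks}")
    for e in record.events:
        if "breakthrough" in e or "majority" in e:
            print(e)


if __name__ == "__main__":
    main()
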