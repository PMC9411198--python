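"""End-to-end pipeline on a synthetic empirical-format dataset.

Generates a dataset with two known strategies — a nearest-neighbour
heuristic group and a strong reinforcement-learning group — writes it to
the empirical CSV schema, reloads it through the validating loader, and
runs the full empirical analysis (learning curves + DET model).
"""

import tempfile
from pathlib import Path

import trapline as tl

cfg = tl.SyntheticConfig(
    array="double_trapezoid",
    groups={"heuristic": "nearest_neighbour", "learner": "reinforcement(2)"},
    n_individuals=12,
    n_trials=60,
    revisit_noise=0.1,
    seed=42,
)
with tempfile.TemporaryDirectory() as tmp:
    path = tl.write_trials_csv(tl.generate_dataset(cfg), Path(tmp) / "trials.csv")
    trials = tl.read_trials_csv(path)
    print(f"loaded {len(trials)} trials; per-group counts: {trials.attrs['counts']}")
    starts = tl.empirical_start_probs(trials)
    print(f"observed start probabilities (heuristic group): {starts['heuristic']}")

    arts = tl.run_empirical_study(
        path,
        {"mcmc": {"n_steps": 500, "burn_steps": 500}, "det_mode": "concatenated"},
        outdir=Path(tmp) / "out",
    )
    post = arts["double_trapezoid"]["learning"]
    for g in post.group_names:
        lo, hi = post.group_ci(g, "slope", 0.95)
        print(f"{g}: slope 95% CI ({lo:+.3f}, {hi:+.3f})")
print(
    "\nThe heuristic group's slope CI straddles zero (no learning, "
    "near-optimal from the start); the learner group's lies below zero."
)
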