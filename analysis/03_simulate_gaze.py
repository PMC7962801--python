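#!/usr/bin/env python
"""Simulate the free-viewing experiment from the planted taxonomy.

64 subjects each view 240 motifs (30 per style, each motif in exactly one
style per subject, Latin-rotated so every stimulus is seen by 8 subjects).
Fixations mix motif content, tree-structured style fields, and center bias.
Writes the fixation log under results/gaze/.
"""

import argparse
from pathlib import Path

from styletax import GazeBehaviorModel, make_gaze_design, simulate_fixations, to_newick
from styletax.io import write_fixations
from styletax.synthetic import default_planted_taxonomy

N_SUBJECTS = 64
MOTIFS_PER_STYLE = 30


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/gaze"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    taxonomy = default_planted_taxonomy()
    design = make_gaze_design(
        taxonomy.styles, MOTIFS_PER_STYLE, seed=args.seed, n_subjects=N_SUBJECTS
    )
    model = GazeBehaviorModel(seed=args.seed)
    fixations = simulate_fixations(design, taxonomy, model)

    write_fixations(fixations, args.out_dir / "fixations.csv")
    (args.out_dir / "planted_tree.nwk").write_text(to_newick(taxonomy.tree) + "\n")
    n_images = MOTIFS_PER_STYLE * len(taxonomy.styles)
    print(f"simulated {len(fixations)} fixations: {N_SUBJECTS} subjects x "
          f"{n_images} stimuli, ~{len(fixations) / (N_SUBJECTS * n_images):.1f} "
          f"fixations per subject per image")
    print(f"wrote {args.out_dir / 'fixations.csv'}")


if __name__ == "__main__":
    main()
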