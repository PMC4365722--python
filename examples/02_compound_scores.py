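"""From raw test scores to oriented z-scored compound scores.

Applies the inclusion screen (MMSE > 26, both HADS subscales < 16),
derives the eight compound scores, z-transforms them over the cohort and
flips the three time-based scores so higher always means better.
"""

from cogtypology import (apply_inclusion, compound_scores, default_spec, generate,
                         standardize_and_orient)

table, _ = generate(default_spec(seed=0))
included, exclusions = apply_inclusion(table)
print(f"{len(included)} of {len(table)} participants pass the screen "
      f"({len(exclusions)} excluded)")

raw = compound_scores(included)
print("\nraw compound scores (first 3 participants):")
print(raw.head(3).round(2).to_string())

cm = standardize_and_orient(raw)
z = cm.to_frame()
print("\noriented z-scores: column means ~0, sds ~1, higher = better")
print(z.describe().loc[["mean", "std"]].round(3).to_string())
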