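"""Generate a synthetic cohort with planted cognitive subgroups.

The default spec plants six subgroups (sizes 23/39/31/26/11/25, total
155) with distinct mean profiles over the eight compound scores and
subgroup-linked covariates. Prints the per-subgroup composition.
"""

from cogtypology import default_spec, generate

spec = default_spec(seed=0)
table, labels = generate(spec)

print(f"generated {len(table)} participants in {len(spec.profiles)} subgroups\n")
for profile in spec.profiles:
    members = table.data.loc[(labels == profile.label).to_numpy()]
    n_young = (members["age_group"] == "young").sum()
    print(f"{profile.label}: n={profile.n_members:3d}  young/old={n_young}/"
          f"{len(members) - n_young:<3d} mean MMSE={members['mmse'].mean():.1f}  "
          f"mean crystallized IQ={members['iq_crystallized'].mean():.1f}")

# Each row is one participant with raw test scores; the hidden subgroup
# label is what the downstream pipeline tries to rediscover.
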