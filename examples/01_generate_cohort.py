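"""Generate a synthetic navigation cohort and apply the inclusion filter.

Builds a participant table (demographics + latent skill), a level catalog,
and per-level trajectory lengths, then applies the study's inclusion rules:
enough completed levels, complete demographics, age <= 70, and countries
with enough players and balanced merged education classes.
"""

import wayfind as w

cfg = w.GeneratorConfig(n_participants=20_000, seed=7)
participants, trajectories, levels = w.simulate_dataset(cfg, n_wayfinding=10)
print(f"simulated {len(participants)} participants x {len(levels)} levels")
print(participants[["participant_id", "age", "gender", "education4",
                    "country", "birth_year"]].head())

cohort, report = w.apply_inclusion(participants, trajectories, levels,
                                   w.InclusionCriteria())
print("\nfilter stages (initial -> completeness -> age -> country):",
      report.stages)
print(report.per_country[["country", "n", "imbalance", "eligible"]]
      .to_string(index=False))
# Each country's imbalance is max/min of the merged education class sizes;
# a country is retained only with >= 500 players and imbalance <= 10.
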