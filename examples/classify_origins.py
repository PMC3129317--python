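"""Classify repeated life-habit origins as parallel or convergent.

Uses the bundled 17-transition table from the scallop study.  A derived habit
with two or more independent origins is 'parallel' when all origins share one
ancestral habit, 'convergent' when every pair of origins has different
ancestors, and 'both' for mixtures.
"""

import habitevol as hv

records = hv.load_table2_records()
classifications = hv.classify(hv.collect_origins(records))

for cls in classifications:
    ancestors = ", ".join(
        hv.state_label(e.ancestral_state) for e in cls.origins
    )
    print(
        f"{hv.state_label(cls.derived_state):<12} {cls.count} origin(s) "
        f"from [{ancestors}] -> {cls.summary}"
    )

n_byssal = hv.count_parallel_from_state(classifications, 2)
print()
print(
    f"{n_byssal} of {len(records)} transitions "
    f"({100 * n_byssal / len(records):.0f}%) arose from byssal ancestors."
)
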