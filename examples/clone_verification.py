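"""Clone dereplication and the polymerase-error verification filter.

Simulates clone libraries (20 clones per template over 2 independent PCRs,
per-site error rate 0.001), collapses them into sequence types, and keeps
only types seen in >= 2 clones from >= 2 PCRs — the standard logic for
excluding polymerase artefacts from cloned amplicon data.
"""

import sedlineage as sl

templates = sl.evolve_sequences(sl.simulate_tree(6, seed=20), 191, 0.08, seed=20)
libraries = [
    sl.simulate_clone_library(seq, clone_count=20, clone_error_rate=0.001,
                              seed=50 + i, sample_id="lake_01", template_id=tid)
    for i, (tid, seq) in enumerate(zip(templates.ids, templates.sequences))
]

types = sl.dereplicate(libraries)
verified, discarded = sl.verify_sequence_types(types, min_clones=2, min_pcrs=2)

print(f"clones sequenced:   {sum(len(lib) for lib in libraries)}")
print(f"sequence types:     {len(types)}")
print(f"verified lineages:  {len(verified)}  (true templates: {len(templates)})")
print()
print("discarded types (likely polymerase errors):")
print(discarded.to_string(index=False))
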