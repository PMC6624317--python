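"""Detect ectopic transcription initiation by the binned NB test.

Runs the full chain on a simulated dataset — 10-nt bins over -995..+995,
core and neighbour exclusions, the spike-normalized negative-binomial exact
test with BH correction, and per-gene ectopic base selection — then scores
the calls against the planted truth.
"""

import numpy as np

from startshift import SimConfig, simulate
from startshift.ectopic import shift_summary
from startshift.experiments import run_ectopic_caller

data = simulate(SimConfig(n_genes=60), seed=7)
calls = run_ectopic_caller(data)

truth = data.truth.set_index("gene_id")
print(f"{'gene':10s} {'planted':>8s} {'called':>8s} {'padj':>9s}")
for c in calls[:8]:
    planted = truth.loc[c.gene_id, "ectopic_offset"]
    planted = "none" if np.isnan(planted) else f"{int(planted):+d}"
    print(f"{c.gene_id:10s} {planted:>8s} {c.offset:+8d} {c.padj:9.2e}")

planted_genes = set(truth.index[truth["shifted"]])
called_genes = {c.gene_id for c in calls}
s = shift_summary(calls)
print()
print(f"planted shifts recovered: {len(called_genes & planted_genes)}"
      f"/{len(planted_genes)}")
print(f"false calls on null genes: {len(called_genes - planted_genes)}")
print(f"median shift distance: {s.median_shift:.0f} nt upstream "
      f"({100 * s.upstream_fraction:.0f}% of calls upstream)")
print()
print("Offsets are strand-relative (negative = upstream); every call is")
print("guaranteed to fall outside the -25..+24 core around the TSS.")
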