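"""Classify promoter nucleosome encroachment from MNase fragments.

Fragments are length-filtered to the mononucleosome range (120-180 nt),
deduplicated, and reduced to midpoint dyad proxies; occupancy over the TSS
core (-25..+24) is compared between conditions with a 1.5-fold threshold.
"""

from startshift import PipelineConfig, SimConfig, simulate
from startshift.experiments import mnase_recovery
from startshift.nucleosome import filter_fragments
from startshift.tracks import fragment_center_track

cfg = PipelineConfig()
data = simulate(SimConfig(n_genes=60), seed=5)

for cond, frags in data.mnase.items():
    kept = filter_fragments(frags, cfg)
    print(f"{cond}: {len(frags)} fragments -> {len(kept)} after the "
          f"120-180 nt filter and deduplication")

r = mnase_recovery(seed=5, sim_cfg=SimConfig(n_genes=60))
print()
print(f"planted nucleosome gains classified encroached: "
      f"{100 * r['planted_encroached_fraction']:.0f}%")
print(f"unplanted promoters falsely flagged: "
      f"{100 * r['unplanted_encroached_fraction']:.0f}%")
print()
print("Encroachment = (KD + 1) / (control + 1) >= 1.5 on depth-normalized")
print("fragment-center counts over the TSS window; the planted knockdown")
print("nucleosome sits directly over the TSS, mimicking NDR collapse.")
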