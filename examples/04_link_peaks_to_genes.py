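"""Link differential peaks to candidate target genes by correlation.

Every differential peak is paired with genes whose TSS lies within 1 Mb
of its summit; the Pearson correlation between peak signal and gene FPKM
across the 6 samples is kept at |r| > 0.8 and P < 0.01 (at n = 6 the
p-threshold corresponds to |r| >~ 0.917).
"""

import pandas as pd

from acetylink.linking import candidate_pairs, distance_decay, select_links
from acetylink.chip import differential_acetylation
from acetylink.rnaseq import CountMatrix, fpkm
from acetylink.simulate import SimConfig, simulate_all

cfg = SimConfig(seed=42)
bundle = simulate_all(cfg)
ann = bundle["annotation"]

peak_res = differential_acetylation(bundle["signal"], cfg.groups)
diff = [m.as_peak() for m in bundle["consensus_peaks"]
        if peak_res.loc[m.id, "label"] != "ns"]

lengths = pd.Series({g.id: g.canonical_transcript().exonic_length
                     for g in ann.genes.values()})
abundance = fpkm(CountMatrix(bundle["rna"], cfg.groups, lengths))

pairs = candidate_pairs(diff, ann, window=1_000_000)
links = select_links(pairs, bundle["signal"].normalized, abundance,
                     peak_directions=peak_res["label"])

print(f"differential peaks : {len(diff)}")
print(f"candidate pairs    : {len(pairs)} (within 1 Mb)")
print(f"selected links     : {len(links)} "
      f"({sum(l.sign == 'positive' for l in links)} positive, "
      f"{sum(l.sign == 'negative' for l in links)} negative)")
mean_kb = sum(l.distance for l in links) / max(len(links), 1) / 1e3
print(f"mean summit-TSS distance: {mean_kb:.1f} kb")
print()
decay = distance_decay(links)
print("links per 100-kb distance bin:")
print(decay[["bin_start", "bin_end", "total"]].to_string(index=False))
# A link's sign says whether acetylation and expression move together;
# distances of hundreds of kb are expected for distal enhancers.
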