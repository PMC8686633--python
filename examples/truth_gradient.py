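"""Long-read truth overlap as a function of mapper support.

Merges four per-mapper call sets (sensitivity 0.85 each, plus independent
private false positives) and scores each support level against a simulated
long-read call set.  False positives rarely co-occur across mappers, so
the overlap rate climbs steeply with support — the signature used to read
singletons as probable false positives.
"""

from svfactor import (FactorKey, MergeConfig, SimulationConfig, merge_callsets,
                      simulate_callset, simulate_longread, simulate_truth,
                      truth_overlap)

MAPPERS = ("BWA-MEM", "Bowtie2", "Isaac", "Stampy")
cfg = SimulationConfig(
    n_loci=800, seed=7, genome=(("chr1", 15_000_000), ("chr2", 15_000_000)),
    base_sensitivity=0.85,
    mapper_sensitivity={m: 1.0 for m in MAPPERS},
    center_sensitivity={c: 1.0 for c in ("Center1", "Center2", "Center3")},
    replicate_noise=0.0, private_fp_rate=60.0,
    recurrent_fp_pools={"mapper": {}, "center": {}},
    jitter_sd={m: 30.0 for m in MAPPERS},
)

truth = simulate_truth(cfg)
sets = [simulate_callset(truth, FactorKey("LCL5", "Center1", "Rep1", m, "dedup"), cfg)
        for m in MAPPERS]
merged = merge_callsets(sets, MergeConfig(max_dist=1000, min_size=0))
longread = simulate_longread(truth, "LCL5", cfg)
cmp_ = truth_overlap(merged, longread)

print(f"{len(merged)} merged clusters vs {len(longread)} long-read calls")
for k in sorted(cmp_.rate_by_support):
    n_hit, n_tot = cmp_.counts_by_support[k]
    print(f"  supported by {k} mapper(s): {n_hit:4d}/{n_tot:4d} "
          f"= {cmp_.rate_by_support[k]:6.2f}% in long-read set")
print("\nLow overlap at support 1 marks mapper-private false positives; at"
      "\nsupport >= 2 the rate jumps to the long-read sensitivity ceiling"
      "\n(~92% here), since nearly all multi-mapper calls are real variants.")
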