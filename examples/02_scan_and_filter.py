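"""Genome-wide motif scan with the full filter cascade.

Mirrors the motif accounting of a binding-site selection analysis: scan both
strands for the consensus motif, drop matches in blacklisted or poorly
mappable regions, flag the "no-signal" (never ChIP-bound) motifs that form
the unbound control universe, and classify CGGAA (methylatable) cores.
"""

from pioneerscan.motifs import (
    classify_cpg_core,
    mappability_filter,
    no_signal_motifs,
    scan_genome,
)
from pioneerscan.simulate import SynthConfig, generate

data = generate(SynthConfig(seed=0, chrom_lengths={"chr1": 500_000},
                            n_motifs=300, atac_library=5e5))

matches = scan_genome(data.pwm, data.genome)
print("raw matches (log-odds >= %.1f):" % data.pwm.threshold, len(matches))

filtered = mappability_filter(matches, data.mappability, data.blacklist)
print("after 200-bp mappability >= 0.8 + blacklist filter:", len(filtered))

no_sig = no_signal_motifs(filtered, [data.chip_pu1])
print("no-signal motifs (<= 3 tags per 10^7 in every sample):", int(no_sig.sum()))

cpg = classify_cpg_core(filtered, data.genome, data.pwm.core_offset)
print("CGGAA-core motifs:", int(cpg['cpg_core'].sum()),
      "| admissible for methylation analysis (no neighbor within 150 bp):",
      int((cpg['cpg_core'] & cpg['meth_set']).sum()))
# Each filter narrows the motif universe exactly as the peak-side filters do,
# so bound/unbound comparisons are not confounded by alignability.
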