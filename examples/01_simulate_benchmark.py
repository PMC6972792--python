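"""Generate a (reduced) synthetic two-condition benchmark and inspect truth.

The generator plants motif instances of four site classes into a random
genome and emits ATAC cut tracks before/after factor induction, ChIP tag
tracks, mappability/conservation/methylation tracks, genes and eQTLs,
together with ground-truth tables.
"""

from pioneerscan.simulate import SynthConfig, generate

config = SynthConfig(
    seed=0,
    chrom_lengths={"chr1": 400_000, "chr2": 400_000},
    n_motifs=400,
    atac_library=4e5,
    n_genes=24,
)
data = generate(config)

truth = data.truth.motifs
primary = truth[~truth["is_pair_partner"]]
print("planted motifs:", len(primary), "(+", truth["is_pair_partner"].sum(), "pair partners)")
print("site classes:", primary["site_class"].value_counts().to_dict())
print(f"bound in truth: {primary['bound'].mean():.1%}")
print("ATAC libraries (cuts): pre=%d post=%d" % (data.atac_pre.total, data.atac_post.total))
print("homotypic pairs planted:", len(data.truth.pairs))
# "bound" follows a logistic model in motif score and pre-accessibility, so
# high-score and pre-accessible motifs are bound most often.
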