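"""Synthetic two-condition (TF-induced vs control) ChIP/ATAC/RNA benchmark.

The generator emulates the statistical structure the analysis assumes for a
non-classical pioneer factor induced in a naive cell type:

* a random background genome with planted motif instances whose log-odds
  scores follow a truncated normal;
* four site classes — de-novo-remodeled candidates (closed before, opened
  when bound), pre-accessible sites, never-bound motifs, and partner-factor
  sites that lose accessibility after induction;
* a logistic binding model in motif score and pre-accessibility, with
  methylated CGGAA motifs suppressed by a configurable factor;
* ATAC cut tracks for both conditions with a footprint-shaped central dip
  at bound motifs, and ChIP tag tracks for the factor and a control;
* homotypic motif pairs co-planted at preferred spacings (15-45 bp) at
  bound sites and at uniform spacings (12-150 bp) at unbound sites;
* partner-class motifs (RUNX/GATA/Ebox) co-planted preferentially near
  low-score bound motifs;
* mappability, conservation and CpG-methylation tracks, a blacklist, gene
  models with expression fold changes coupled to remodeled domains, and an
  eQTL table.

Every draw derives from a single seed through named sub-streams, so the
output is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as psio
from .intervals import IntervalSet
from .motifs import BASES, PWM
from .tracks import SignalTrack

_STREAMS = [
    "genome", "placement", "scores", "classes", "binding", "pairs",
    "partners", "atac_pre", "atac_post", "chip", "conservation",
    "methylation", "genes", "eqtl",
]


def surrogate_pu1_pwm() -> PWM:
    """A 12-bp ETS-like surrogate PWM (consensus AAAGAGGAAGTG, GGAA core at
    offset 5) shipped for tests and simulation; position 4 admits the C that
    creates the methylatable CGGAA variant."""
    consensus = "AAAGAGGAAGTG"
    # secondary probabilities rotate by position so mismatch penalties form a
    # fine ladder, letting planted sequences approximate arbitrary scores
    minor_patterns = [(0.13, 0.07, 0.04), (0.10, 0.08, 0.06), (0.15, 0.05, 0.04)]
    probs = np.zeros((12, 4))
    for i, b in enumerate(consensus):
        minors = minor_patterns[i % len(minor_patterns)]
        order = [j for j in range(4) if j != BASES.index(b)]
        probs[i, BASES.index(b)] = 1.0 - sum(minors)
        for j, p in zip(order[i % 3 :] + order[: i % 3], minors):
            probs[i, j] = p
    probs[4] = [0.60, 0.25, 0.10, 0.05]  # A C G T; C -> CGGAA variant
    return PWM(name="PU1_surrogate", probs=probs, threshold=6.0, core_offset=5)


def partner_pwms() -> dict[str, PWM]:
    """Small known-motif library for the co-associated factor classes."""
    out = {}
    for name, consensus in (("RUNX", "TGTGGTTT"), ("GATA", "AGATAAGA"),
                            ("EBOX", "ACAGCTGT")):
        probs = np.full((len(consensus), 4), 0.04)
        for i, b in enumerate(consensus):
            probs[i] = 0.04
            probs[i, BASES.index(b)] = 0.88
        out[name] = PWM(name=name, probs=probs, threshold=7.0)
    return out


@dataclass
class SynthConfig:
    """Frozen study conditions for the synthetic benchmark."""

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    gc: float = 0.41
    n_motifs: int = 2000
    # planted log-odds score distribution (truncated normal)
    score_mean: float = 10.0
    score_sd: float = 2.0
    score_min: float = 6.5
    # site-class proportions
    class_proportions: dict = field(default_factory=lambda: {
        "de_novo": 0.25, "pre_accessible": 0.15, "unbound": 0.55, "lost": 0.05,
    })
    # binding model: P(bound) = sigmoid(b0 + bs*(score - score_ref) + ba*log2(1 + pre_amp))
    beta0: float = 0.2
    beta_score: float = 0.8
    beta_access: float = 0.12
    score_ref: float = 10.0
    # accessibility
    acc_cuts: float = 600.0        # expected cuts per accessible site
    remodel_cuts: float = 600.0    # additional cuts gained by bound de-novo sites
    acc_sd: float = 60.0           # Gaussian spread of site accessibility
    atac_bg_rate: float = 0.08     # background cut rate per base (pre-scaling)
    atac_library: float = 1_000_000.0  # expected cuts per ATAC library
    footprint_dip: float = 0.4     # multiplicative central depletion at bound motifs
    # ChIP
    chip_bg_rate: float = 0.0005
    chip_amp: float = 80.0
    chip_sd: float = 40.0
    # homotypic pairs
    pair_rate_bound: float = 0.9
    pair_rate_unbound: float = 0.35
    pair_band_bound: tuple = (15, 45)
    pair_band_unbound: tuple = (12, 150)
    # partner-class co-planting
    co_rate_bound_lowscore: float = 0.6
    co_rate_other: float = 0.15
    # methylation
    cggaa_fraction: float = 0.2
    methylated_fraction: float = 0.5
    methylation_suppression: float = 0.25
    # genes / expression
    n_genes: int = 60
    expressed_fraction: float = 0.85
    expression_fold: float = 1.8
    expression_noise_sd: float = 0.15
    n_eqtls: int = 60

    def validate(self) -> None:
        errors = []
        if self.seed < 0:
            errors.append("seed must be >= 0")
        if not self.chrom_lengths or any(v < 10_000 for v in self.chrom_lengths.values()):
            errors.append("chrom_lengths: each chromosome must be >= 10 kb")
        if not 0 < self.gc < 1:
            errors.append("gc must be in (0, 1)")
        if self.n_motifs < 0:
            errors.append("n_motifs must be >= 0")
        if not np.isclose(sum(self.class_proportions.values()), 1.0):
            errors.append("class_proportions must sum to 1")
        for name in ("pair_rate_bound", "pair_rate_unbound", "co_rate_bound_lowscore",
                     "co_rate_other", "cggaa_fraction", "methylated_fraction",
                     "methylation_suppression", "expressed_fraction", "footprint_dip"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errors.append(f"{name} must be in [0, 1]")
        if self.atac_library <= 0:
            errors.append("atac_library must be positive")
        if errors:
            raise ValueError("invalid SynthConfig: " + "; ".join(errors))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["pair_band_bound"] = list(d["pair_band_bound"])
        d["pair_band_unbound"] = list(d["pair_band_unbound"])
        return json.dumps(d, indent=2)


def benchmark_config(seed: int = 0) -> SynthConfig:
    """The frozen benchmark conditions: 2 Mb over 2 chromosomes, 2000 planted
    motifs (25% de-novo-remodeled candidates, 15% pre-accessible, 55%
    never-bound, 5% lost partner sites), 10^6 cuts per ATAC library."""
    cfg = SynthConfig(seed=seed)
    cfg.validate()
    return cfg


@dataclass
class TruthTables:
    motifs: pd.DataFrame   # planted motif instances with class/bound/methylation truth
    pairs: pd.DataFrame    # planted homotypic pair spacings
    genes: pd.DataFrame    # per-gene true fold change


@dataclass
class SynthData:
    config: SynthConfig
    genome: dict
    chrom_sizes: dict
    pwm: PWM
    partner_pwms: dict
    blacklist: IntervalSet
    mappability: SignalTrack
    conservation: SignalTrack
    methylation: SignalTrack
    atac_pre: SignalTrack
    atac_post: SignalTrack
    chip_pu1: SignalTrack
    chip_control: SignalTrack
    genes: pd.DataFrame
    eqtls: pd.DataFrame
    truth: TruthTables

    def write(self, outdir: str) -> dict:
        """Emit all inputs in standard text formats; returns path map."""
        psio.ensure_dir(outdir)
        paths = {}

        def _p(name):
            paths[name] = f"{outdir}/{name}"
            return paths[name]

        psio.write_fasta(self.genome, _p("genome.fa"))
        psio.write_bed(self.blacklist, _p("blacklist.bed"), ["chrom", "start", "end"])
        for name in ("mappability", "conservation", "methylation",
                     "atac_pre", "atac_post", "chip_pu1", "chip_control"):
            psio.write_bedgraph(getattr(self, name), _p(f"{name}.bedgraph"))
        self.pwm.write(_p("pu1.pwm"))
        for cname, pwm in self.partner_pwms.items():
            pwm.write(_p(f"{cname}.pwm"))
        self.genes.to_csv(_p("genes.tsv"), sep="\t", index=False)
        self.eqtls.to_csv(_p("eqtls.tsv"), sep="\t", index=False)
        self.truth.motifs.to_csv(_p("truth_motifs.tsv"), sep="\t", index=False)
        self.truth.pairs.to_csv(_p("truth_pairs.tsv"), sep="\t", index=False)
        self.truth.genes.to_csv(_p("truth_genes.tsv"), sep="\t", index=False)
        with open(f"{outdir}/config.json", "w") as fh:
            fh.write(self.config.to_json())
        paths["config.json"] = f"{outdir}/config.json"
        return paths


# -- helpers ---------------------------------------------------------------


def _sequence_for_score(pwm: PWM, target: float, rng: np.random.Generator,
                        force_cpg: bool) -> np.ndarray:
    """Construct motif codes whose log-odds score approximates ``target``.

    Starts from the consensus and walks mutable positions (outside the GGAA
    core and the CpG-determining base) in random order, introducing the
    mismatch whose score drop best consumes the remaining deficit.
    """
    lod = pwm.log_odds[:, :4]
    w = pwm.width
    core = pwm.core_offset
    codes = lod.argmax(axis=1).astype(int)
    if force_cpg:
        codes[core - 1] = BASES.index("C")
    fixed = set(range(core - 1, core + 4))  # CpG base + GGAA core
    score = float(lod[np.arange(w), codes].sum())
    deficit = score - target
    for p in rng.permutation([i for i in range(w) if i not in fixed]):
        if abs(deficit) <= 0.05:
            break
        drops = lod[p, codes[p]] - lod[p]  # 0 for the current base
        allowed = drops <= deficit + 0.35  # cap overshoot below the target
        cand = np.flatnonzero(allowed)
        if not len(cand):  # target above what this (e.g. CpG) variant can reach
            break
        b = int(cand[np.argmin(np.abs(deficit - drops[cand]))])
        deficit -= drops[b]
        codes[p] = b
    return codes


def _complement(codes: np.ndarray) -> np.ndarray:
    return 3 - codes


def _add_gaussian(rate: np.ndarray, center: int, total: float, sd: float) -> None:
    span = int(4 * sd)
    x = np.arange(-span, span + 1)
    kernel = np.exp(-0.5 * (x / sd) ** 2)
    kernel = kernel / kernel.sum() * total
    lo, hi = center - span, center + span + 1
    s, e = max(lo, 0), min(hi, len(rate))
    if e > s:
        rate[s:e] += kernel[s - lo : s - lo + (e - s)]


def _fixed_regions(length: int, fractions, size: int) -> list[tuple[int, int]]:
    return [(int(f * length), int(f * length) + size) for f in fractions]


# -- generator -------------------------------------------------------------


def generate(config: SynthConfig) -> SynthData:
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = dict(zip(_STREAMS, (np.random.default_rng(s) for s in ss.spawn(len(_STREAMS)))))

    pwm = surrogate_pu1_pwm()
    partners = partner_pwms()
    w = pwm.width
    chroms = list(config.chrom_lengths)
    sizes = dict(config.chrom_lengths)

    # background genome as base codes
    pbase = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    codes = {c: rngs["genome"].choice(4, size=n, p=pbase).astype(np.int8)
             for c, n in sizes.items()}

    # blacklist and low-mappability regions at fixed genome fractions
    bl_rows, lm_rows = [], []
    for c, n in sizes.items():
        bl_rows += [(c, s, e) for s, e in _fixed_regions(n, (0.10, 0.35, 0.60, 0.85), 2000)]
        lm_rows += [(c, s, e) for s, e in _fixed_regions(n, (0.22, 0.47, 0.72, 0.93), 2000)]
    blacklist = IntervalSet.from_records(bl_rows)
    mappability = SignalTrack({c: np.ones(n) for c, n in sizes.items()})
    for c, s, e in lm_rows:
        mappability[c][s:e] = 0.3

    # candidate slots, excluding blacklist/low-mappability neighborhoods
    excluded = IntervalSet.from_records(bl_rows + lm_rows).merge(0)
    slots = []
    for c, n in sizes.items():
        cov = excluded.coverage_array(c, n)
        for p in range(1500, n - 1500, 700):
            if not cov[p - 350 : p + 350].any():
                slots.append((c, p))
    if config.n_motifs > len(slots):
        raise ValueError(f"n_motifs={config.n_motifs} exceeds {len(slots)} available slots")
    order = rngs["placement"].permutation(len(slots))[: config.n_motifs]
    jitter = rngs["placement"].integers(-100, 101, size=config.n_motifs)
    sites = [(slots[i][0], int(slots[i][1] + j)) for i, j in zip(order, jitter)]

    # planted scores, CpG variants, classes
    n = config.n_motifs
    lo = (config.score_min - config.score_mean) / config.score_sd
    from scipy import stats as _st
    targets = _st.truncnorm.rvs(
        lo, (pwm.max_score - 0.2 - config.score_mean) / config.score_sd,
        loc=config.score_mean, scale=config.score_sd, size=n,
        random_state=rngs["scores"],
    ) if n else np.array([])
    cggaa = rngs["scores"].random(n) < config.cggaa_fraction
    methylated = cggaa & (rngs["methylation"].random(n) < config.methylated_fraction)
    class_names = list(config.class_proportions)
    probs = np.array([config.class_proportions[k] for k in class_names])
    site_class = np.array(class_names)[rngs["classes"].choice(len(class_names), size=n, p=probs)]
    strands = np.where(rngs["placement"].random(n) < 0.5, "+", "-")

    # realised motif sequences written into the genome
    realized = np.zeros(n)
    lod = pwm.log_odds[:, :4]
    for i, (chrom, start) in enumerate(sites):
        mcodes = _sequence_for_score(pwm, targets[i], rngs["scores"], bool(cggaa[i]))
        realized[i] = float(lod[np.arange(w), mcodes].sum())
        if strands[i] == "+":
            codes[chrom][start : start + w] = mcodes
        else:
            codes[chrom][start : start + w] = _complement(mcodes)[::-1]

    # binding model
    pre_amp = np.where(np.isin(site_class, ["pre_accessible", "lost"]), config.acc_cuts, 0.0)
    logit = (config.beta0 + config.beta_score * (realized - config.score_ref)
             + config.beta_access * np.log2(1 + pre_amp))
    p_bound = 1.0 / (1.0 + np.exp(-logit))
    p_bound[methylated] *= config.methylation_suppression
    bound = rngs["binding"].random(n) < p_bound
    bound[np.isin(site_class, ["unbound", "lost"])] = False
    remodeled = (site_class == "de_novo") & bound

    # homotypic partner motifs
    pair_rows = []
    partner_sites = []  # (chrom, start, strand, codes, parent index)
    for i, (chrom, start) in enumerate(sites):
        if bound[i]:
            rate, band = config.pair_rate_bound, config.pair_band_bound
        elif site_class[i] == "unbound":
            rate, band = config.pair_rate_unbound, config.pair_band_unbound
        else:
            continue
        if rngs["pairs"].random() >= rate:
            continue
        d = int(rngs["pairs"].integers(band[0], band[1] + 1))
        pstart = start + d
        ptarget = float(np.clip(rngs["pairs"].normal(config.score_mean, config.score_sd),
                                config.score_min, pwm.max_score - 0.2))
        pcodes = _sequence_for_score(pwm, ptarget, rngs["pairs"], False)
        pstrand = "+" if rngs["pairs"].random() < 0.5 else "-"
        gcodes = pcodes if pstrand == "+" else _complement(pcodes)[::-1]
        codes[chrom][pstart : pstart + w] = gcodes
        partner_sites.append((chrom, pstart, pstrand, pcodes, i))
        pair_rows.append((chrom, start, pstart, d, bool(bound[i])))
    truth_pairs = pd.DataFrame(
        pair_rows, columns=["chrom", "start_a", "start_b", "distance", "bound"]
    )

    # partner-class motifs near low-score bound motifs (and some others)
    median_score = float(np.median(realized)) if n else 0.0
    pnames = sorted(partners)
    for i, (chrom, start) in enumerate(sites):
        rate = (config.co_rate_bound_lowscore
                if bound[i] and realized[i] < median_score else config.co_rate_other)
        if rngs["partners"].random() >= rate:
            continue
        cname = pnames[int(rngs["partners"].integers(len(pnames)))]
        ppwm = partners[cname]
        center_dist = int(rngs["partners"].integers(14, 81))
        pcenter = start + w // 2 - center_dist  # upstream, clear of homotypic partners
        pstart = pcenter - ppwm.width // 2
        inst = np.array([rngs["partners"].choice(4, p=row) for row in ppwm.probs])
        if rngs["partners"].random() < 0.5:
            codes[chrom][pstart : pstart + ppwm.width] = inst
        else:
            codes[chrom][pstart : pstart + ppwm.width] = _complement(inst)[::-1]

    # genome to strings
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    genome = {c: lut[codes[c].astype(np.intp)].tobytes().decode() for c in chroms}

    # -- ATAC tracks -------------------------------------------------------
    def _atac_track(post: bool, rng: np.random.Generator) -> SignalTrack:
        # site bumps at exactly the configured amplitudes; the uniform
        # background absorbs the remainder of the library-size target
        bump = {c: np.zeros(nn) for c, nn in sizes.items()}
        for i, (chrom, start) in enumerate(sites):
            center = start + w // 2
            amp = 0.0
            if site_class[i] == "pre_accessible":
                amp = config.acc_cuts
            elif site_class[i] == "lost":
                amp = 0.0 if post else config.acc_cuts
            elif site_class[i] == "de_novo" and post and bound[i]:
                amp = config.remodel_cuts
            if amp > 0:
                _add_gaussian(bump[chrom], center, amp, config.acc_sd)
        genome_len = sum(sizes.values())
        bump_total = sum(b.sum() for b in bump.values())
        bg_rate = max((config.atac_library - bump_total) / genome_len,
                      config.atac_bg_rate)
        rate = {c: b + bg_rate for c, b in bump.items()}

        def _dip(chrom: str, start: int) -> None:
            rate[chrom][start - 2 : start + w + 2] *= config.footprint_dip

        for i, (chrom, start) in enumerate(sites):
            accessible_now = (
                site_class[i] == "pre_accessible"
                or (post and site_class[i] == "de_novo" and bound[i])
            )
            if bound[i] and accessible_now:
                _dip(chrom, start)
        # bound homotypic partners are protected too
        for chrom, pstart, _strand, _codes, parent in partner_sites:
            accessible_now = (
                site_class[parent] == "pre_accessible"
                or (post and site_class[parent] == "de_novo" and bound[parent])
            )
            if bound[parent] and accessible_now:
                _dip(chrom, pstart)
        data = {c: rng.poisson(r).astype(float) for c, r in rate.items()}
        return SignalTrack.from_counts(data)

    atac_pre = _atac_track(post=False, rng=rngs["atac_pre"])
    atac_post = _atac_track(post=True, rng=rngs["atac_post"])

    # -- ChIP tracks -------------------------------------------------------
    chip_rate = {c: np.full(nn, config.chip_bg_rate, dtype=float) for c, nn in sizes.items()}
    for i, (chrom, start) in enumerate(sites):
        if bound[i]:
            _add_gaussian(chip_rate[chrom], start + w // 2, config.chip_amp, config.chip_sd)
    chip_pu1 = SignalTrack.from_counts(
        {c: rngs["chip"].poisson(r).astype(float) for c, r in chip_rate.items()}
    )
    chip_control = SignalTrack.from_counts(
        {c: rngs["chip"].poisson(np.full(nn, config.chip_bg_rate)).astype(float)
         for c, nn in sizes.items()}
    )

    # -- conservation ------------------------------------------------------
    cons = {c: rngs["conservation"].beta(1.5, 8.0, size=nn) for c, nn in sizes.items()}
    for i, (chrom, start) in enumerate(sites):
        if bound[i]:
            bump = 0.30 + 0.10 * rngs["conservation"].random()
            seg = slice(max(start - 2, 0), start + w + 2)
            cons[chrom][seg] = np.clip(cons[chrom][seg] + bump, 0, 1)
    conservation = SignalTrack(cons)

    # -- methylation ratio track ------------------------------------------
    meth = {c: np.zeros(nn) for c, nn in sizes.items()}
    for c in chroms:
        cc = codes[c]
        cpg = np.flatnonzero((cc[:-1] == 1) & (cc[1:] == 2))  # C followed by G
        vals = rngs["methylation"].beta(0.7, 0.7, size=len(cpg))
        meth[c][cpg] = vals
        meth[c][cpg + 1] = vals
    for i, (chrom, start) in enumerate(sites):
        if not cggaa[i]:
            continue
        if strands[i] == "+":
            cpos = start + pwm.core_offset - 1
        else:
            cpos = start + w - 1 - pwm.core_offset
        ratio = (0.80 + 0.15 * rngs["methylation"].random() if methylated[i]
                 else 0.02 + 0.13 * rngs["methylation"].random())
        meth[chrom][cpos : cpos + 2] = ratio
    methylation = SignalTrack(meth)

    # -- genes, expression, eQTLs -----------------------------------------
    per_chrom = max(config.n_genes // len(chroms), 1)
    gene_rows = []
    gid = 0
    for c, nn in sizes.items():
        grid = np.arange(40_000, nn - 40_000, (nn - 80_000) // max(per_chrom, 1))
        tss = np.sort(rngs["genes"].choice(grid, size=min(per_chrom, len(grid)), replace=False))
        for t in tss:
            gid += 1
            gene_rows.append((f"G{gid:04d}", c, "+" if rngs["genes"].random() < 0.5 else "-",
                              int(t), bool(rngs["genes"].random() < config.expressed_fraction)))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss", "expressed"])

    from .geneassign import build_domains
    domains = build_domains(genes, chrom_sizes=sizes)
    remodeled_centers = [(sites[i][0], sites[i][1] + w // 2)
                         for i in range(n) if remodeled[i]]
    affected = []
    for row in domains.itertuples(index=False):
        hit = any(c == row.chrom and row.start <= p < row.end for c, p in remodeled_centers)
        affected.append(row.gene_id if hit else None)
    affected_ids = {g for g in affected if g}
    control_expr = rngs["genes"].lognormal(np.log(50.0), 0.8, size=len(genes))
    noise = rngs["genes"].lognormal(0.0, config.expression_noise_sd, size=len(genes))
    fold = np.where(genes["gene_id"].isin(affected_ids), config.expression_fold, 1.0)
    genes["control"] = control_expr
    genes["induced"] = control_expr * fold * noise
    truth_genes = genes[["gene_id"]].copy()
    truth_genes["true_fold"] = fold
    truth_genes["affected"] = genes["gene_id"].isin(affected_ids)

    eq_rows = []
    expressed = genes[genes["expressed"]]
    for _ in range(config.n_eqtls):
        c = chroms[int(rngs["eqtl"].integers(len(chroms)))]
        pos = int(rngs["eqtl"].integers(10_000, sizes[c] - 10_000))
        cand = expressed[expressed["chrom"] == c]["gene_id"].to_numpy()
        if not len(cand):
            continue
        k = int(rngs["eqtl"].integers(1, min(3, len(cand)) + 1))
        ids = sorted(rngs["eqtl"].choice(cand, size=k, replace=False).tolist())
        eq_rows.append((c, pos, ",".join(ids)))
    eqtls = pd.DataFrame(eq_rows, columns=["chrom", "pos", "gene_ids"])

    # -- truth tables ------------------------------------------------------
    motif_rows = []
    for i, (chrom, start) in enumerate(sites):
        motif_rows.append((chrom, start, start + w, strands[i], float(realized[i]),
                           site_class[i], bool(bound[i]), bool(remodeled[i]),
                           bool(cggaa[i]), bool(methylated[i]), False, i))
    for chrom, pstart, pstrand, pcodes, parent in partner_sites:
        motif_rows.append((chrom, pstart, pstart + w, pstrand,
                           float(lod[np.arange(w), pcodes].sum()), site_class[parent],
                           bool(bound[parent]), False, False, False, True, parent))
    truth_motifs = pd.DataFrame(
        motif_rows,
        columns=["chrom", "start", "end", "strand", "score", "site_class", "bound",
                 "remodeled", "cggaa", "methylated", "is_pair_partner", "site_index"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    return SynthData(
        config=config, genome=genome, chrom_sizes=sizes, pwm=pwm,
        partner_pwms=partners, blacklist=blacklist, mappability=mappability,
        conservation=conservation, methylation=methylation,
        atac_pre=atac_pre, atac_post=atac_post,
        chip_pu1=chip_pu1, chip_control=chip_control,
        genes=genes, eqtls=eqtls,
        truth=TruthTables(motifs=truth_motifs, pairs=truth_pairs, genes=truth_genes),
    )
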