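"""Synthetic genomes, gene models, mutation sets and feature tracks.

The generator plants known structure so that every downstream statistic
has a ground truth: a per-context baseline mutation rate (uniform, an
explicit k-mer matrix, or a mixture of trinucleotide signatures), a
TSS-proximal rate excess of configurable fold and extent, coding-strand
mutational asymmetries on transcribed sequence, purifying selection on
nonsynonymous coding sites, and dataset/allele-frequency labels drawn by
configured fractions.

Randomness is stream-separated: the genome, the mutations and the feature
tracks each consume an independent child of the configured seed, so the
same genome can carry independent mutation replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import ContextMatrix
from .genome import BASES, Genome
from .selection import NONSYN, per_site_effects
from .signatures import channel_table

_GENOME_STREAM, _MUTATION_STREAM, _TRACK_STREAM = 0, 1, 2


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.41
    n_genes: int = 8
    gene_length_range: tuple[int, int] = (8_000, 12_000)
    gene_types: tuple[str, ...] = ("protein_coding",)
    baseline_matrix: ContextMatrix | str = "uniform"
    baseline_rate: float = 1e-3       # mean per-site total rate for "uniform"/signature modes
    hotspot_fold: float = 1.0
    hotspot_halfwidth: int = 1_000
    hotspot_decay: str = "box"        # "box" | "exponential"
    hotspot_anchor: str = "TSS"       # "TTS" available as a negative control
    strand_bias_fold: dict = field(default_factory=dict)   # e.g. {"C>T": 2.0}, coding strand
    signatures: pd.DataFrame | None = None                 # 96-channel matrix, columns = signatures
    signature_mixture: dict | None = None                  # name -> weight, sums to 1
    selection_nonsyn_retention: float = 1.0
    mosaic_fraction: float = 0.0
    dnm_fraction: float = 0.0
    af_class_probs: dict = field(default_factory=lambda: {"<0.01%": 1.0})
    gene_rate_sd: float = 0.0         # lognormal sd of per-gene regional rate multipliers
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "selection_nonsyn_retention", "mosaic_fraction", "dnm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hotspot_fold < 0:
            raise ValueError("hotspot_fold must be >= 0")
        if self.hotspot_decay not in ("box", "exponential"):
            raise ValueError("hotspot_decay must be 'box' or 'exponential'")
        if self.mosaic_fraction + self.dnm_fraction > 1.0:
            raise ValueError("mosaic_fraction + dnm_fraction must be <= 1")
        if self.signature_mixture is not None:
            if abs(sum(self.signature_mixture.values()) - 1.0) > 1e-9:
                raise ValueError("signature_mixture must sum to 1")
            if self.signatures is None:
                raise ValueError("signature_mixture requires a signatures matrix")
        if abs(sum(self.af_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("af_class_probs must sum to 1")

    def stream(self, which: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[which])


def simulate_genome(config: SimulationConfig):
    """Random genome plus non-overlapping gene models and CDS annotations.

    Genes are spread evenly over chromosomes with equal intergenic gaps;
    every protein-coding gene carries a central single-exon CDS whose
    length is a multiple of 3.  Byte-identical across runs for a fixed
    seed.
    """
    rng = config.stream(_GENOME_STREAM)
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for c in range(config.n_chroms):
        seqs[f"chr{c + 1}"] = rng.choice(4, size=config.chrom_length, p=p).astype(np.uint8)
    genome = Genome(seqs)

    per_chrom = np.zeros(config.n_chroms, dtype=int)
    for g in range(config.n_genes):
        per_chrom[g % config.n_chroms] += 1
    lo, hi = config.gene_length_range
    gene_rows, cds_rows = [], []
    gid = 0
    for c in range(config.n_chroms):
        k = per_chrom[c]
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        gap = (config.chrom_length - int(lengths.sum())) // (k + 1)
        if gap < 1:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small for {k} genes of "
                f"lengths up to {hi} on chr{c + 1}")
        pos = gap
        for L in lengths:
            strand = "+" if rng.random() < 0.5 else "-"
            gtype = config.gene_types[gid % len(config.gene_types)]
            gene_id = f"g{gid:05d}"
            gene_rows.append((gene_id, f"chr{c + 1}", pos, pos + int(L), strand, gtype))
            if gtype == "protein_coding":
                cds_len = (int(L) // 2 // 3) * 3
                cstart = pos + (int(L) - cds_len) // 2
                cds_rows.append((gene_id, f"chr{c + 1}", cstart, cstart + cds_len, strand))
            pos += int(L) + gap
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"])
    cds = pd.DataFrame(cds_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return genome, genes, cds


def _baseline_rates(config: SimulationConfig, genome: Genome, chrom: str,
                    strand_of: np.ndarray) -> np.ndarray:
    """(L, 4) per-site per-genomic-alt baseline rates; zero where undefined."""
    L = genome.length(chrom)
    rates = np.zeros((L, 4), dtype=np.float64)
    if config.signature_mixture is not None:
        # mixture over 96 pyrimidine-collapsed channels; the mixture profile
        # sets the relative (trinuc, alt) rates, scaled so that the mean
        # per-site total rate over uniformly abundant contexts is baseline_rate
        chan = channel_table()
        prof = np.zeros(96)
        for name, w in config.signature_mixture.items():
            prof += w * config.signatures[name].to_numpy()
        prof = prof / prof.sum()
        rate_cell = np.zeros((64, 4))  # by plus-strand trinuc code and genomic alt
        for row, q in zip(chan.itertuples(), prof):
            rate_cell[row.ctx_code, row.alt_code] += q
            rate_cell[row.rc_ctx_code, 3 - row.alt_code] += q
        rate_cell *= 32 * config.baseline_rate
        ctx = genome.context_codes(chrom, 3, "+")
        ok = ctx >= 0
        rates[ok] = rate_cell[ctx[ok]]
        return rates
    if isinstance(config.baseline_matrix, ContextMatrix):
        mat = config.baseline_matrix
    else:
        mat = ContextMatrix.uniform(5, config.baseline_rate)
    m = mat.m
    for s, sval in (("+", 0), ("-", 1)):
        sel = strand_of == sval
        if not sel.any():
            continue
        ctx = genome.context_codes(chrom, mat.k, s)
        ok = sel & (ctx >= 0)
        rows = m[ctx[ok]]
        rates[ok] = rows if s == "+" else rows[:, ::-1]
    return rates


_TYPE_CODES = {f"{r}>{a}": (BASES.index(r), BASES.index(a))
               for r in BASES for a in BASES if r != a}


def simulate_mutations(genome: Genome, genes: pd.DataFrame, config: SimulationConfig,
                       cds: pd.DataFrame | None = None):
    """Draw mutations site by site from the planted rate model.

    Per site and alternate allele the probability is the baseline matrix
    entry for the site's (coding-strand) context, multiplied by the
    hotspot fold near the configured anchor, by the strand-bias folds on
    transcribed sites, and by the nonsynonymous retention inside CDS.  At
    most one mutation arises per site.  Returns ``(mutations, info)``
    where info counts sites skipped for undefined contexts.
    """
    rng = config.stream(_MUTATION_STREAM)
    eff = per_site_effects(cds, genome) if cds is not None and len(cds) else None
    rows = []
    n_skipped = 0
    gene_mult = {}
    if config.gene_rate_sd > 0:
        sd = config.gene_rate_sd
        for gid in genes["gene_id"]:
            gene_mult[gid] = float(np.exp(rng.normal(-sd * sd / 2, sd)))
    for chrom in genome.chroms:
        L = genome.length(chrom)
        gsub = genes[genes.chrom == chrom]
        strand_of = np.zeros(L, dtype=np.int8)  # orientation for context reading
        transcribed = np.zeros(L, dtype=bool)
        for g in gsub.itertuples(index=False):
            strand_of[g.start:g.end] = 0 if g.strand == "+" else 1
            transcribed[g.start:g.end] = True
        rates = _baseline_rates(config, genome, chrom, strand_of)
        n_skipped += int((rates.sum(axis=1) == 0).sum())

        if config.hotspot_fold != 1.0:
            mult = np.ones(L)
            hw = config.hotspot_halfwidth
            for g in gsub.itertuples(index=False):
                if config.hotspot_anchor == "TSS":
                    a = g.start if g.strand == "+" else g.end - 1
                else:
                    a = g.end - 1 if g.strand == "+" else g.start
                if config.hotspot_decay == "box":
                    mult[max(0, a - hw): a + hw + 1] = config.hotspot_fold
                else:
                    lo, hi = max(0, a - 8 * hw), min(L, a + 8 * hw + 1)
                    d = np.abs(np.arange(lo, hi) - a)
                    mult[lo:hi] = np.maximum(
                        mult[lo:hi], 1.0 + (config.hotspot_fold - 1.0) * np.exp(-d / hw))
            rates *= mult[:, None]

        if gene_mult:
            mult = np.ones(L)
            for g in gsub.itertuples(index=False):
                mult[g.start:g.end] = gene_mult[g.gene_id]
            rates *= mult[:, None]

        for tname, fold in config.strand_bias_fold.items():
            r, a = _TYPE_CODES[tname]
            codes = genome.seqs[chrom]
            plus = transcribed & (strand_of == 0) & (codes == r)
            rates[plus, a] *= fold
            minus = transcribed & (strand_of == 1) & (codes == 3 - r)
            rates[minus, 3 - a] *= fold

        if eff is not None and config.selection_nonsyn_retention != 1.0:
            rates[eff[chrom] == NONSYN] *= config.selection_nonsyn_retention

        total = rates.sum(axis=1)
        np.clip(total, 0.0, 0.999, out=total)
        u = rng.random(L)
        hit = np.flatnonzero(u < total)
        if len(hit) == 0:
            continue
        r4 = rates[hit]
        cum = np.cumsum(r4, axis=1)
        draw = rng.random(len(hit)) * cum[:, -1]
        alt = (draw[:, None] >= cum).sum(axis=1)
        refs = genome.seqs[chrom][hit]
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": hit,
            "ref": [BASES[c] for c in refs],
            "alt": [BASES[c] for c in alt],
        }))
    if rows:
        muts = pd.concat(rows, ignore_index=True)
    else:
        muts = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    n = len(muts)
    p_ds = [config.mosaic_fraction, config.dnm_fraction,
            1.0 - config.mosaic_fraction - config.dnm_fraction]
    ds = rng.choice(["mosaic", "dnm", "erv"], size=n, p=p_ds) if n else []
    classes = list(config.af_class_probs)
    af = rng.choice(classes, size=n, p=list(config.af_class_probs.values())) if n else []
    muts["dataset"] = ds
    muts["af_class"] = af
    info = {"n_mutations": n, "n_sites_skipped": n_skipped}
    return muts, info


def simulate_feature_tracks(genome: Genome, genes: pd.DataFrame, config: SimulationConfig,
                            features=("dsb", "replication_timing"), bin_size: int = 1_000,
                            dsb_correlation: float = 0.5, rt_domain_length: int = 300_000,
                            rt_slope: float = 0.02) -> dict[str, pd.DataFrame]:
    """bedGraph-style tracks with known relationships to the planted hotspot.

    The replication-timing track is a piecewise-linear triangle wave with
    the requested domain length and slope.  The DSB-like track is a
    standard-normal signal mixed with the standardized TSS-hotspot
    indicator at the requested correlation.
    """
    rng = config.stream(_TRACK_STREAM)
    out = {}
    for feat in features:
        frames = []
        for chrom in genome.chroms:
            L = genome.length(chrom)
            starts = np.arange(0, L, bin_size)
            ends = np.minimum(starts + bin_size, L)
            mid = (starts + ends) // 2
            if feat == "replication_timing":
                phase = mid % (2 * rt_domain_length)
                val = np.where(phase < rt_domain_length, phase, 2 * rt_domain_length - phase)
                val = val * rt_slope
            elif feat == "dsb":
                ind = np.zeros(len(mid))
                hw = config.hotspot_halfwidth
                gsub = genes[genes.chrom == chrom]
                for g in gsub.itertuples(index=False):
                    a = g.start if g.strand == "+" else g.end - 1
                    ind[np.abs(mid - a) <= hw] = 1.0
                if ind.std() > 0:
                    ind = (ind - ind.mean()) / ind.std()
                rho = dsb_correlation
                val = rho * ind + np.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(len(mid))
            else:
                val = rng.standard_normal(len(mid))
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": val}))
        out[feat] = pd.concat(frames, ignore_index=True)
    return out
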