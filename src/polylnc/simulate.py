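"""Truth-bearing miniature of a diploid-hybrid-allopolyploid study design.

Two "diploid" genomes (A and D) share a syntenic protein-coding-gene
scaffold with configurable sequence divergence; lncRNA loci are planted
with known TE overlap, synteny class (ST / SA / SYN_PCG / NON_SYN),
hybrid expression class (Equal / Up / Down relative to the in silico
mid-parent) and per-context methylation change.  The F1 genome is the
concatenation of A and D; the allotetraploid relabels the two
subgenomes.  Every planted property is recorded in a truth table so
downstream stages can be scored by parameter recovery.

Expression counts are negative-binomial at locus level; methylation is
per-cytosine binomial with class-dependent baselines; small-RNA reads
are drawn from a per-bp weight map with transposon bodies enriched and
lncRNA-overlapped transposons depleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import longest_orf_codons
from .core import (
    CountMatrix,
    GenomicInterval,
    PolylncError,
    TEFeature,
    TranscriptModel,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_CODONS = ("TAA", "TAG", "TGA")


def _default_te_density() -> dict[str, float]:
    # Gypsy-dominant landscape; LINEs a small share of the genome
    return {
        "Gypsy": 0.18,
        "Copia": 0.06,
        "LTR_other": 0.03,
        "DNA": 0.05,
        "LINE": 0.02,
        "SINE": 0.01,
        "unknown": 0.03,
    }


def _default_meth_baseline() -> dict[str, dict[str, float]]:
    # per feature class, per context methylation probability
    return {
        "intergenic": {"CG": 0.55, "CHG": 0.35, "CHH": 0.07},
        "pcg": {"CG": 0.30, "CHG": 0.08, "CHH": 0.03},
        "lnc": {"CG": 0.40, "CHG": 0.25, "CHH": 0.08},
        "te": {"CG": 0.85, "CHG": 0.70, "CHH": 0.10},
        "lnc_te_gypsy": {"CG": 0.70, "CHG": 0.55, "CHH": 0.08},
        "lnc_te_line": {"CG": 0.25, "CHG": 0.20, "CHH": 0.05},
        "lnc_te_other": {"CG": 0.50, "CHG": 0.40, "CHH": 0.07},
    }


def _default_family_probs() -> dict[str, dict[str, float]]:
    # family mix of the planted lncRNA-overlapping TE, by synteny class:
    # LINEs skewed toward ST loci, Gypsy toward SA loci
    return {
        "ST": {"Gypsy": 0.15, "LINE": 0.50, "Copia": 0.10, "DNA": 0.10,
               "LTR_other": 0.05, "SINE": 0.05, "unknown": 0.05},
        "SA": {"Gypsy": 0.50, "LINE": 0.15, "Copia": 0.10, "DNA": 0.10,
               "LTR_other": 0.05, "SINE": 0.05, "unknown": 0.05},
        "other": {"Gypsy": 0.30, "LINE": 0.35, "Copia": 0.10, "DNA": 0.10,
                  "LTR_other": 0.05, "SINE": 0.05, "unknown": 0.05},
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic study design, with defaults that
    emulate the statistical structure of a two-diploid + hybrid cotton
    comparison at desk scale."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_pcg: int = 100
    n_lnc: int = 120
    te_density: dict[str, float] = field(default_factory=_default_te_density)
    frac_te_overlapped_lnc: float = 2.0 / 3.0
    frac_sa: float = 0.8
    frac_syn_pcg: float = 0.05
    frac_non_syn: float = 0.25
    frac_nat: float = 0.08
    frac_intronic: float = 0.04
    frac_f1_reprogrammed: float = 1.0 / 3.0
    reprogram_log2fc_lo: float = 1.0
    reprogram_log2fc_hi: float = 3.0
    nb_dispersion: float = 0.1
    read_depth: int = 300_000
    n_reps: int = 2
    div_lnc: float = 0.12
    div_pcg: float = 0.03
    pcg_orf_codons: int = 250
    meth_baseline: dict = field(default_factory=_default_meth_baseline)
    demeth_effect: float = 0.3
    meth_expr_rho_target: float = -0.6
    meth_depth: float = 12.0
    te_family_probs: dict = field(default_factory=_default_family_probs)
    srna_n_reads: int = 60_000
    srna_te_body_weight: float = 5.0
    srna_background_weight: float = 1.0
    srna_pcg_body_weight: float = 0.5
    srna_pcg_flank_weight: float = 1.5
    srna_lnc_te_depletion: float = 0.3

    def validate(self) -> None:
        for name in ("frac_te_overlapped_lnc", "frac_sa", "frac_syn_pcg",
                     "frac_non_syn", "frac_nat", "frac_intronic",
                     "frac_f1_reprogrammed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PolylncError(f"{name}={v} outside [0, 1]")
        if self.frac_syn_pcg + self.frac_non_syn > 1.0:
            raise PolylncError("synteny class fractions exceed 1")
        if self.frac_nat + self.frac_intronic > 0.5:
            raise PolylncError("NAT + intronic fractions implausibly large")
        dens = sum(self.te_density.values())
        if dens >= 0.6:
            raise PolylncError(f"TE densities sum to {dens:.2f} >= 0.6")
        slots = (self.n_pcg + self.n_lnc) / self.n_chroms
        spacing = self.chrom_length / (slots + 1)
        if spacing < 3200:
            raise PolylncError(
                "chromosomes too short for the requested gene/lncRNA count"
            )


@dataclass
class SimulatedDataset:
    """Everything the generator plants, plus the truth table."""

    config: SimConfig
    genomes: dict[str, dict[str, str]]          # "A"/"D" -> chrom -> seq
    pcg: dict[str, list[TranscriptModel]]       # per genome
    lnc: dict[str, list[TranscriptModel]]       # annotated lncRNA per genome
    tes: dict[str, list[TEFeature]]             # per genome
    truth: pd.DataFrame                          # one row per lnc locus

    def f1_genome(self) -> dict[str, str]:
        return {**self.genomes["A"], **self.genomes["D"]}

    def allotetraploid_genome(self) -> dict[str, str]:
        out = {}
        for g, prefix in (("A", "AT_"), ("D", "DT_")):
            for chrom, seq in self.genomes[g].items():
                out[prefix + chrom] = seq
        return out

    def chrom_lengths(self, genome: str) -> dict[str, int]:
        return {c: len(s) for c, s in self.genomes[genome].items()}

    def locus_span(self, locus_id: str) -> GenomicInterval:
        row = self.truth.loc[locus_id]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]),
                               row["strand"])

    def locus_sequence(self, locus_id: str) -> str:
        row = self.truth.loc[locus_id]
        seq = self.genomes[row["genome"]][row["chrom"]]
        return seq[int(row["start"]):int(row["end"])]


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _noncoding_seq(rng: np.random.Generator, n: int, max_tries: int = 40) -> str:
    """Random sequence rejected until no ORF reaches 100 codons."""

    for _ in range(max_tries):
        s = _random_seq(rng, n)
        if longest_orf_codons(s) < 100:
            return s
    raise PolylncError(f"could not draw a non-coding sequence of length {n}")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    idx = np.where(hit)[0]
    for i in idx:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _mutate_noncoding(seq: str, rate: float, rng: np.random.Generator,
                      max_tries: int = 40) -> str:
    for _ in range(max_tries):
        s = _mutate(seq, rate, rng)
        if longest_orf_codons(s) < 100:
            return s
    raise PolylncError("mutation kept producing coding-looking sequence")


def _orf_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + non-stop codons + TAA."""

    codons = []
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _mutate_orf(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute at ``rate`` but revert any codon that becomes a stop
    (and keep the initial ATG), preserving the open reading frame."""

    mutated = _mutate(seq, rate, rng)
    out = [mutated[i:i + 3] for i in range(0, len(mutated) - 2, 3)]
    orig = [seq[i:i + 3] for i in range(0, len(seq) - 2, 3)]
    out[0] = orig[0]
    for i in range(1, len(out) - 1):
        if out[i] in _STOP_CODONS:
            out[i] = orig[i]
    return "".join(out) + mutated[len(out) * 3:]


# ---------------------------------------------------------------------------
# genome simulation

@dataclass
class _LncPlan:
    locus_id: str
    chrom: str
    slot_center: int
    class_code: str          # u / x / i
    synteny: str             # ST / SA / SYN_PCG / NON_SYN / NA (x, i)
    te_family: str | None
    length: int
    n_exons: int
    strand: str


def _plan_lnc_classes(cfg: SimConfig, rng: np.random.Generator):
    """Deterministic-count planting of class, synteny and TE status."""

    n = cfg.n_lnc
    n_nat = int(round(cfg.frac_nat * n))
    n_intr = int(round(cfg.frac_intronic * n))
    n_linc = n - n_nat - n_intr
    n_syn_pcg = int(round(cfg.frac_syn_pcg * n_linc))
    n_non_syn = int(round(cfg.frac_non_syn * n_linc))
    n_syntenic = n_linc - n_syn_pcg - n_non_syn
    n_sa = int(round(cfg.frac_sa * n_syntenic))
    n_st = n_syntenic - n_sa

    codes = ["x"] * n_nat + ["i"] * n_intr + ["u"] * n_linc
    synteny = (["NA"] * (n_nat + n_intr) + ["ST"] * n_st + ["SA"] * n_sa
               + ["SYN_PCG"] * n_syn_pcg + ["NON_SYN"] * n_non_syn)
    order = rng.permutation(n)
    codes = [codes[i] for i in order]
    synteny = [synteny[i] for i in order]

    n_te = int(round(cfg.frac_te_overlapped_lnc * n))
    te_flag = np.zeros(n, dtype=bool)
    te_flag[rng.choice(n, size=n_te, replace=False)] = True
    return codes, synteny, te_flag


def _draw_family(probs: Mapping[str, float], rng: np.random.Generator) -> str:
    fams = sorted(probs)
    p = np.array([probs[f] for f in fams], dtype=float)
    p /= p.sum()
    return str(rng.choice(fams, p=p))


_LNC_TE_LEN = {
    "Gypsy": (800, 2000), "Copia": (600, 1500), "LTR_other": (500, 1200),
    "LINE": (700, 1600), "SINE": (150, 400), "DNA": (400, 1200),
    "unknown": (300, 1000), "other": (300, 1000),
}

_BG_TE_LEN = {
    "Gypsy": (1200, 4000), "Copia": (800, 2500), "LTR_other": (600, 2000),
    "LINE": (800, 2200), "SINE": (120, 400), "DNA": (500, 1800),
    "unknown": (300, 1200), "other": (300, 1200),
}


def simulate_genomes(cfg: SimConfig) -> SimulatedDataset:
    """Build genomes A and D, annotations, TE features and the truth table.

    Genome D shares the A gene order (fully collinear scaffold); PCG
    sequences diverge at ``div_pcg`` with reading frames preserved, lncRNA
    homologs at ``div_lnc``.  SA loci keep a sequence homolog in D but no
    D transcript; NON_SYN loci have no D homolog; SYN_PCG loci derive
    their sequence from the flanking coding gene so their best cross-
    genome hit lands in a coding exon.
    """

    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_counts, rng_meth, rng_srna = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]

    codes, synteny, te_flag = _plan_lnc_classes(cfg, rng_genome)

    n_pcg_c = cfg.n_pcg // cfg.n_chroms
    # NAT / intronic candidates ride on PCGs, not in their own slots
    lnc_slots = [i for i, c in enumerate(codes) if c == "u"]
    n_linc_c = -(-len(lnc_slots) // cfg.n_chroms)  # ceil

    genomes: dict[str, dict[str, str]] = {"A": {}, "D": {}}
    pcg: dict[str, list[TranscriptModel]] = {"A": [], "D": []}
    lnc: dict[str, list[TranscriptModel]] = {"A": [], "D": []}
    tes: dict[str, list[TEFeature]] = {"A": [], "D": []}
    truth_rows: list[dict] = []

    linc_iter = iter(lnc_slots)
    host_targets = [i for i, c in enumerate(codes) if c in ("x", "i")]
    # spread NAT/intronic hosts roughly evenly over chromosomes
    hosts_per_chrom = [host_targets[i::cfg.n_chroms] for i in range(cfg.n_chroms)]

    pcg_idx = 0
    for ci in range(cfg.n_chroms):
        chrom_a, chrom_d = f"A{ci + 1:02d}", f"D{ci + 1:02d}"
        chrom_linc = [next(linc_iter, None) for _ in range(n_linc_c)]
        chrom_linc = [x for x in chrom_linc if x is not None]
        slots = ["P"] * n_pcg_c + ["L"] * len(chrom_linc)
        order = rng_genome.permutation(len(slots))
        slots = [slots[i] for i in order]
        # force coding genes at both chromosome ends so every lncRNA slot
        # lies inside the anchor span
        if slots[0] != "P":
            swap = slots.index("P")
            slots[0], slots[swap] = slots[swap], slots[0]
        if slots[-1] != "P":
            swap = max(i for i in range(1, len(slots)) if slots[i] == "P")
            slots[-1], slots[swap] = slots[swap], slots[-1]

        spacing = cfg.chrom_length // (len(slots) + 1)
        seq_a = np.frombuffer(_random_seq(rng_genome, cfg.chrom_length).encode(),
                              dtype="S1").copy()
        seq_d = np.frombuffer(_random_seq(rng_genome, cfg.chrom_length).encode(),
                              dtype="S1").copy()

        occupied: list[tuple[int, int]] = []
        chrom_pcgs: list[TranscriptModel] = []
        linc_q = list(chrom_linc)

        for si, kind in enumerate(slots):
            center = (si + 1) * spacing + int(
                rng_genome.integers(-spacing // 6, spacing // 6 + 1)
            )
            if kind == "P":
                pcg_idx += 1
                tid = f"PCG{pcg_idx:04d}"
                strand = "+" if rng_genome.random() < 0.5 else "-"
                orf = _orf_seq(rng_genome, cfg.pcg_orf_codons)
                e1_len = (len(orf) * 2 // 5) // 3 * 3
                intron_len = int(rng_genome.integers(700, 1100))
                e2_len = len(orf) - e1_len
                span_len = e1_len + intron_len + e2_len
                start = max(0, center - span_len // 2)
                exon1 = GenomicInterval(chrom_a, start, start + e1_len, strand)
                intron = (start + e1_len, start + e1_len + intron_len)
                exon2 = GenomicInterval(chrom_a, intron[1], intron[1] + e2_len,
                                        strand)
                spliced = orf if strand == "+" else _revcomp(orf)
                seq_a[exon1.start:exon1.end] = np.frombuffer(
                    spliced[:e1_len].encode(), dtype="S1")
                seq_a[exon2.start:exon2.end] = np.frombuffer(
                    spliced[e1_len:].encode(), dtype="S1")
                seq_a[intron[0]:intron[1]] = np.frombuffer(
                    _noncoding_seq(rng_genome, intron_len).encode(), dtype="S1")
                # D copy: frame-preserving divergence, same coordinates
                orf_d = _mutate_orf(orf, cfg.div_pcg, rng_genome)
                spliced_d = orf_d if strand == "+" else _revcomp(orf_d)
                seq_d[exon1.start:exon1.end] = np.frombuffer(
                    spliced_d[:e1_len].encode(), dtype="S1")
                seq_d[exon2.start:exon2.end] = np.frombuffer(
                    spliced_d[e1_len:].encode(), dtype="S1")
                seq_d[intron[0]:intron[1]] = np.frombuffer(
                    _mutate(_decode(seq_a[intron[0]:intron[1]]), cfg.div_lnc,
                            rng_genome).encode(), dtype="S1")
                for genome, chrom in (("A", chrom_a), ("D", chrom_d)):
                    span = GenomicInterval(chrom, exon1.start, exon2.end, strand)
                    exs = [
                        GenomicInterval(chrom, exon1.start, exon1.end, strand),
                        GenomicInterval(chrom, exon2.start, exon2.end, strand),
                    ]
                    pcg[genome].append(
                        TranscriptModel(f"{genome}_{tid}.1", f"{genome}_{tid}",
                                        span, exs, biotype="PCG")
                    )
                occupied.append((exon1.start, exon2.end))
                chrom_pcgs.append(pcg["A"][-1])
            else:
                li = linc_q.pop(0)
                _plant_linc(
                    cfg, rng_genome, li, codes[li], synteny[li], te_flag[li],
                    chrom_a, chrom_d, center, seq_a, seq_d, chrom_pcgs,
                    genomes_out=(genomes, pcg, lnc, tes), occupied=occupied,
                    truth_rows=truth_rows,
                )

        # NAT / intronic lncRNAs on this chromosome's PCGs (one per host gene)
        host_genes = rng_genome.choice(
            len(chrom_pcgs), size=min(len(hosts_per_chrom[ci]), len(chrom_pcgs)),
            replace=False,
        )
        for nxt, hg in zip(hosts_per_chrom[ci], host_genes):
            _plant_hosted(cfg, rng_genome, nxt, codes[nxt], te_flag[nxt],
                          chrom_a, chrom_pcgs[int(hg)], seq_a, lnc, tes,
                          truth_rows)

        # background TEs in the gaps, mirrored coordinates in D
        _plant_background_tes(cfg, rng_genome, chrom_a, chrom_d, occupied, tes)

        genomes["A"][chrom_a] = _decode(seq_a)
        genomes["D"][chrom_d] = _decode(seq_d)

    truth = pd.DataFrame(truth_rows).set_index("locus_id", drop=False)
    ds = SimulatedDataset(cfg, genomes, pcg, lnc, tes, truth)
    _plant_expression(ds, rng_counts)
    _plant_methylation_deltas(ds, rng_meth)
    ds._rng_counts = rng_counts          # reused by simulate_counts
    ds._rng_meth = rng_meth
    ds._rng_srna = rng_srna
    return ds


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _plant_linc(cfg, rng, li, code, syn, has_te, chrom_a, chrom_d, center,
                seq_a, seq_d, chrom_pcgs, genomes_out, occupied, truth_rows):
    genomes, pcg, lnc, tes = genomes_out
    locus_id = f"A_LNC{li + 1:04d}"
    strand = "+" if rng.random() < 0.5 else "-"
    length = int(rng.integers(500, 1600))
    start = max(0, center - length // 2)
    end = start + length

    n_exons = 2 if (length >= 900 and rng.random() < 0.3) else 1
    exons_a = _make_exons(chrom_a, start, end, strand, n_exons, rng)

    def draw_seq() -> str:
        if syn == "SYN_PCG":
            # sequence borrowed from the nearest planted coding gene so the
            # best cross-genome hit falls in a coding exon of D
            donor = min(chrom_pcgs,
                        key=lambda p: abs((p.interval.start + p.interval.end)
                                          // 2 - center))
            dseq = genomes_d_exon_seq(seq_d, donor)
            core = dseq[: min(len(dseq), length - 100)]
            return (_mutate_noncoding_guard(core, cfg.div_lnc, rng)
                    + _noncoding_seq(rng, length - len(core)))
        return _noncoding_seq(rng, length)

    # splice junctions can create ORFs absent from the unspliced sequence;
    # reject on the spliced product so planted candidates pass the filter
    for _ in range(40):
        seq = draw_seq()
        spliced = "".join(seq[e.start - start:e.end - start] for e in exons_a)
        if longest_orf_codons(spliced) < 100:
            break
    seq_a[start:end] = np.frombuffer(seq.encode(), dtype="S1")

    if syn in ("ST", "SA"):
        seq_d[start:end] = np.frombuffer(
            _mutate_noncoding_guard(seq, cfg.div_lnc, rng).encode(), dtype="S1"
        )
    # NON_SYN: D keeps its own random background sequence (no homolog)
    span_a = GenomicInterval(chrom_a, start, end, strand)
    lnc["A"].append(
        TranscriptModel(f"{locus_id}.1", locus_id, span_a, exons_a,
                        biotype="lncRNA_candidate")
    )
    partner_id = ""
    if syn == "ST":
        partner_id = f"D_LNC{li + 1:04d}"
        exons_d = [GenomicInterval(chrom_d, e.start, e.end, e.strand)
                   for e in exons_a]
        lnc["D"].append(
            TranscriptModel(f"{partner_id}.1", partner_id,
                            GenomicInterval(chrom_d, start, end, strand),
                            exons_d, biotype="lncRNA_candidate")
        )

    family = te_id = None
    if has_te:
        probs = cfg.te_family_probs.get(syn, cfg.te_family_probs["other"])
        family = _draw_family(probs, rng)
        lo, hi = _LNC_TE_LEN[family]
        te_len = int(min(rng.integers(lo, hi + 1), length - 60))
        first_exon = exons_a[0]
        te_start = first_exon.start + 20
        te_id = f"TE_{locus_id}"
        te_iv = GenomicInterval(chrom_a, te_start,
                                min(te_start + te_len, end - 20), ".")
        tes["A"].append(TEFeature(te_iv, family, te_id))
        tes["D"].append(
            TEFeature(GenomicInterval(chrom_d, te_iv.start, te_iv.end, "."),
                      family, "D_" + te_id)
        )

    occupied.append((start, end))
    truth_rows.append(_truth_row(locus_id, "A", chrom_a, start, end, strand,
                                 "u", syn, family, te_id, partner_id))
    if syn == "ST":
        truth_rows.append(
            _truth_row(partner_id, "D", chrom_d, start, end, strand, "u",
                       "ST", family, te_id, locus_id)
        )


def genomes_d_exon_seq(seq_d: np.ndarray, donor: TranscriptModel) -> str:
    e = donor.exons[-1]
    return _decode(seq_d[e.start:e.end])


def _mutate_noncoding_guard(seq: str, rate: float, rng) -> str:
    try:
        return _mutate_noncoding(seq, rate, rng)
    except PolylncError:
        return _mutate(seq, rate, rng)


def _make_exons(chrom, start, end, strand, n_exons, rng):
    if n_exons == 1:
        return [GenomicInterval(chrom, start, end, strand)]
    intron_len = int(rng.integers(200, 400))
    e1_len = (end - start - intron_len) // 2
    return [
        GenomicInterval(chrom, start, start + e1_len, strand),
        GenomicInterval(chrom, start + e1_len + intron_len, end, strand),
    ]


def _plant_hosted(cfg, rng, li, code, has_te, chrom_a, host, seq_a, lnc, tes,
                  truth_rows):
    """Plant a NAT (antisense over an exon) or intronic lncRNA on a PCG."""

    locus_id = f"A_LNC{li + 1:04d}"
    if code == "x":
        # short enough that the sense-strand ORF fragment it straddles
        # stays below the coding-potential threshold
        exon = host.exons[-1]
        length = min(max(250, len(exon) - 40), 260)
        start = exon.start + 10
        strand = "-" if host.strand == "+" else "+"
    else:  # intronic
        intron = host.introns[0]
        length = min(max(220, len(intron) - 120), 500)
        start = intron.start + 50
        strand = host.strand
    end = start + length
    span = GenomicInterval(chrom_a, start, end, strand)
    lnc["A"].append(
        TranscriptModel(f"{locus_id}.1", locus_id, span, [span],
                        biotype="lncRNA_candidate")
    )
    family = te_id = None
    if has_te:
        family = _draw_family(cfg.te_family_probs["other"], rng)
        te_id = f"TE_{locus_id}"
        te_iv = GenomicInterval(chrom_a, start + 10,
                                min(start + 10 + 300, end - 5), ".")
        tes["A"].append(TEFeature(te_iv, family, te_id))
    truth_rows.append(_truth_row(locus_id, "A", chrom_a, start, end, strand,
                                 code, "NA", family, te_id, ""))


def _truth_row(locus_id, genome, chrom, start, end, strand, code, syn,
               family, te_id, partner):
    return {
        "locus_id": locus_id,
        "genome": genome,
        "chrom": chrom,
        "start": start,
        "end": end,
        "strand": strand,
        "class_code": code,
        "synteny_truth": syn,
        "te_family": family if family else "none",
        "te_id": te_id or "",
        "partner_locus": partner,
    }


def _plant_background_tes(cfg, rng, chrom_a, chrom_d, occupied, tes):
    occ = sorted(occupied)
    gaps = []
    prev = 0
    for s, e in occ:
        if s - prev > 400:
            gaps.append([prev + 100, s - 100])
        prev = max(prev, e)
    if cfg.chrom_length - prev > 400:
        gaps.append([prev + 100, cfg.chrom_length - 100])

    idx = 0
    for family in sorted(cfg.te_density):
        target = cfg.te_density[family] * cfg.chrom_length
        placed = 0
        tries = 0
        lo, hi = _BG_TE_LEN[family]
        while placed < target and tries < 400 and gaps:
            tries += 1
            gi = int(rng.integers(0, len(gaps)))
            gs, ge = gaps[gi]
            avail = ge - gs
            if avail < max(200, lo // 2):
                continue
            te_len = int(min(rng.integers(lo, hi + 1), avail))
            start = int(rng.integers(gs, ge - te_len + 1))
            idx += 1
            te_id = f"bg_{family}_{chrom_a}_{idx}"
            tes["A"].append(
                TEFeature(GenomicInterval(chrom_a, start, start + te_len, "."),
                          family, te_id)
            )
            tes["D"].append(
                TEFeature(GenomicInterval(chrom_d, start, start + te_len, "."),
                          family, "D_" + te_id)
            )
            placed += te_len
            # split the gap
            left = [gs, start - 50]
            right = [start + te_len + 50, ge]
            gaps.pop(gi)
            for g in (left, right):
                if g[1] - g[0] > 300:
                    gaps.append(g)


# ---------------------------------------------------------------------------
# expression planting and count simulation

def _plant_expression(ds: SimulatedDataset, rng: np.random.Generator) -> None:
    cfg = ds.config
    truth = ds.truth
    n = len(truth)
    # lognormal relative expression, lncRNA lower than PCGs by design
    base = np.exp(rng.normal(np.log(1.0), 0.6, size=n))
    truth["base_mean"] = base
    truth["expressed_self"] = True

    lnc_ids = list(truth.index)
    n_rep = int(round(cfg.frac_f1_reprogrammed * len(lnc_ids)))
    chosen = rng.choice(len(lnc_ids), size=n_rep, replace=False)
    up = set(chosen[: n_rep // 2])
    down = set(chosen[n_rep // 2:])
    classes = []
    log2fc = np.zeros(n)
    for i in range(n):
        if i in up:
            classes.append("Up")
            log2fc[i] = rng.uniform(cfg.reprogram_log2fc_lo,
                                    cfg.reprogram_log2fc_hi)
        elif i in down:
            classes.append("Down")
            log2fc[i] = -rng.uniform(cfg.reprogram_log2fc_lo,
                                     cfg.reprogram_log2fc_hi)
        else:
            classes.append("Equal")
    truth["f1_class_truth"] = classes
    truth["planted_log2fc"] = log2fc


def _nb_sample(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 1e-9:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(ds: SimulatedDataset,
                    rng: np.random.Generator | None = None) -> CountMatrix:
    """NB locus-level counts for parents, F1 and allotetraploid replicates.

    Locus universe: every annotated lncRNA locus in A and D plus every
    coding gene.  Parent samples express only their own genome's loci;
    F1 and allotetraploid samples express both, at mid-parent level for
    Equal loci and at mid-parent x 2^planted_log2fc for reprogrammed
    loci.  Coding genes are four-fold higher expressed than lncRNA and
    always Equal.
    """

    cfg = ds.config
    rng = rng if rng is not None else getattr(ds, "_rng_counts",
                                              np.random.default_rng(cfg.seed))
    truth = ds.truth
    lnc_ids = list(truth.index)
    pcg_ids = [t.locus_id for g in ("A", "D") for t in ds.pcg[g]]
    pcg_loci = sorted(set(pcg_ids))
    pcg_base = {l: float(np.exp(rng.normal(np.log(4.0), 0.6))) for l in pcg_loci}

    universe = lnc_ids + pcg_loci
    genome_of = {l: truth.at[l, "genome"] for l in lnc_ids}
    genome_of.update({l: l.split("_")[0] for l in pcg_loci})
    base = {l: float(truth.at[l, "base_mean"]) for l in lnc_ids}
    base.update(pcg_base)
    f1_dev = {l: float(truth.at[l, "planted_log2fc"]) for l in lnc_ids}
    f1_dev.update({l: 0.0 for l in pcg_loci})

    total_rel = sum(base.values())
    scale = cfg.read_depth / total_rel

    cols = {}
    sizes = {}
    for rep in range(1, cfg.n_reps + 1):
        for sample, kind in (("Ga", "A"), ("Gr", "D"), ("F1", "F1"),
                             ("Gh", "F1")):
            name = f"{sample}_rep{rep}"
            mean = np.zeros(len(universe))
            for i, l in enumerate(universe):
                if kind in ("A", "D"):
                    if genome_of[l] == kind:
                        mean[i] = base[l] * scale
                else:
                    mid = base[l] * scale / 2.0
                    mean[i] = mid * (2.0 ** f1_dev[l])
            cols[name] = _nb_sample(rng, mean, cfg.nb_dispersion)
            sizes[name] = cfg.read_depth
    counts = pd.DataFrame(cols, index=universe)
    return CountMatrix(counts, pd.Series(sizes))


# ---------------------------------------------------------------------------
# methylation planting and simulation

def _plant_methylation_deltas(ds: SimulatedDataset,
                              rng: np.random.Generator) -> None:
    """Gaussian-copula coupling of methylation change to expression change.

    Reprogrammed loci receive a per-context methylation delta whose
    Spearman correlation with the planted log2FC is the configured
    target (negative: activated loci lose methylation).  Equal loci get
    small zero-centred jitter.
    """

    cfg = ds.config
    truth = ds.truth
    n = len(truth)
    deltas = np.zeros((n, 3))
    rep_mask = (truth["f1_class_truth"] != "Equal").to_numpy()
    x = truth.loc[rep_mask, "planted_log2fc"].to_numpy()
    m = int(rep_mask.sum())
    if m >= 5:
        from scipy.stats import spearmanr

        rho_s = cfg.meth_expr_rho_target
        ranks = pd.Series(x).rank().to_numpy()
        u = _normal_scores(ranks)
        eps = rng.normal(size=m)

        # calibrate the mixing weight on this dataset so the realised
        # sample Spearman matches the target (at small m the stochastic
        # copula alone realises it too loosely)
        def realised(w):
            g = w * u + np.sqrt(max(0.0, 1.0 - w * w)) * eps
            return spearmanr(g, x).statistic

        # realised() is increasing in w: bisect to the target
        lo, hi = -1.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if realised(mid) < rho_s:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-4:
                break
        w = 0.5 * (lo + hi)
        g = w * u + np.sqrt(max(0.0, 1.0 - w * w)) * eps
        base_delta = cfg.demeth_effect * np.tanh(g)
        deltas[rep_mask, 0] = base_delta
        deltas[rep_mask, 1] = 0.8 * base_delta
        deltas[rep_mask, 2] = 0.6 * base_delta
    deltas[~rep_mask] = rng.normal(0.0, 0.01, size=((~rep_mask).sum(), 3))
    truth["delta_meth_CG"] = deltas[:, 0]
    truth["delta_meth_CHG"] = deltas[:, 1]
    truth["delta_meth_CHH"] = deltas[:, 2]


def _normal_scores(ranks: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(ranks / (len(ranks) + 1.0))


def _context_arrays(seq: str):
    """Cytosine positions, strands and contexts from the actual sequence."""

    arr = np.frombuffer(seq.encode(), dtype="S1")
    out_pos, out_strand, out_ctx = [], [], []
    c_pos = np.where(arr == b"C")[0]
    g_pos = np.where(arr == b"G")[0]
    n = len(arr)
    for p in c_pos:
        if p + 1 < n and arr[p + 1] == b"G":
            ctx = "CG"
        elif p + 2 < n and arr[p + 2] == b"G":
            ctx = "CHG"
        else:
            ctx = "CHH"
        out_pos.append(p)
        out_strand.append("+")
        out_ctx.append(ctx)
    for p in g_pos:
        if p - 1 >= 0 and arr[p - 1] == b"C":
            ctx = "CG"
        elif p - 2 >= 0 and arr[p - 2] == b"C":
            ctx = "CHG"
        else:
            ctx = "CHH"
        out_pos.append(p)
        out_strand.append("-")
        out_ctx.append(ctx)
    order = np.argsort(np.array(out_pos, dtype=np.int64), kind="stable")
    return (np.array(out_pos, dtype=np.int64)[order],
            np.array(out_strand)[order],
            np.array(out_ctx)[order])


def _paint_classes(ds: SimulatedDataset, genome: str, chrom: str) -> np.ndarray:
    """Per-bp feature class for baseline methylation lookup."""

    L = len(ds.genomes[genome][chrom])
    cls = np.zeros(L, dtype=np.int8)  # 0 intergenic
    CODE = {"intergenic": 0, "pcg": 1, "lnc": 2, "te": 3,
            "lnc_te_gypsy": 4, "lnc_te_line": 5, "lnc_te_other": 6}
    for t in ds.pcg[genome]:
        if t.chrom == chrom:
            cls[t.interval.start:t.interval.end] = CODE["pcg"]
    for t in ds.lnc[genome]:
        if t.chrom == chrom:
            cls[t.interval.start:t.interval.end] = CODE["lnc"]
    lnc_spans = [(t.interval.start, t.interval.end) for t in ds.lnc[genome]
                 if t.chrom == chrom]
    for te in ds.tes[genome]:
        if te.interval.chrom != chrom:
            continue
        s, e = te.interval.start, te.interval.end
        inside_lnc = any(s < le and ls < e for ls, le in lnc_spans)
        if inside_lnc:
            if te.family == "Gypsy":
                cls[s:e] = CODE["lnc_te_gypsy"]
            elif te.family == "LINE":
                cls[s:e] = CODE["lnc_te_line"]
            else:
                cls[s:e] = CODE["lnc_te_other"]
        else:
            cls[s:e] = CODE["te"]
    return cls


_CLASS_NAMES = ["intergenic", "pcg", "lnc", "te",
                "lnc_te_gypsy", "lnc_te_line", "lnc_te_other"]


def simulate_methylome(ds: SimulatedDataset,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, pd.DataFrame]:
    """Per-cytosine binomial methylation for 'parent' and 'F1' samples.

    Both samples cover the joint F1 genome (A plus D chromosomes); the
    parent sample is the concatenation of the two parental methylomes.
    In the F1, every cytosine within a reprogrammed lncRNA locus has its
    methylation probability shifted by the planted per-context delta.
    Returns frames with columns chrom, pos, strand, context, n_meth,
    n_total.
    """

    cfg = ds.config
    rng = rng if rng is not None else getattr(ds, "_rng_meth",
                                              np.random.default_rng(cfg.seed + 1))
    ctx_index = {"CG": 0, "CHG": 1, "CHH": 2}
    base_tab = np.array(
        [[cfg.meth_baseline[cn][cx] for cx in ("CG", "CHG", "CHH")]
         for cn in _CLASS_NAMES]
    )
    delta_cols = ["delta_meth_CG", "delta_meth_CHG", "delta_meth_CHH"]

    frames: dict[str, list[pd.DataFrame]] = {"parent": [], "F1": []}
    for genome in ("A", "D"):
        for chrom in sorted(ds.genomes[genome]):
            seq = ds.genomes[genome][chrom]
            pos, strand, ctx = _context_arrays(seq)
            cls = _paint_classes(ds, genome, chrom)
            ctx_i = np.array([ctx_index[c] for c in ctx])
            pi = base_tab[cls[pos], ctx_i]

            delta = np.zeros(len(pos))
            sub = ds.truth[(ds.truth["chrom"] == chrom)
                           & (ds.truth["f1_class_truth"] != "Equal")]
            for _, row in sub.iterrows():
                sel = (pos >= row["start"]) & (pos < row["end"])
                if not sel.any():
                    continue
                d = np.array([row[c] for c in delta_cols])
                delta[sel] += d[ctx_i[sel]]

            n_total = rng.poisson(cfg.meth_depth, size=len(pos))
            for sample, shift in (("parent", 0.0), ("F1", 1.0)):
                p = np.clip(pi + shift * delta, 0.005, 0.995)
                n_meth = rng.binomial(n_total, p)
                frames[sample].append(
                    pd.DataFrame({
                        "chrom": chrom, "pos": pos, "strand": strand,
                        "context": ctx, "n_meth": n_meth, "n_total": n_total,
                    })
                )
    return {k: pd.concat(v, ignore_index=True) for k, v in frames.items()}


# ---------------------------------------------------------------------------
# small RNA simulation

def simulate_srna(ds: SimulatedDataset,
                  rng: np.random.Generator | None = None) -> list:
    """Sample 20-25 nt reads from a per-bp weight map.

    TE bodies are strongly enriched, coding-gene bodies depleted with
    enriched flanks, and lncRNA-overlapped TEs depleted relative to
    genome-wide TEs.  Reads in TE bodies get Poisson-inflated
    multi-mapping multiplicities with a small tail beyond 50 loci.
    """

    from .profiles import SrnaRead

    cfg = ds.config
    rng = rng if rng is not None else getattr(ds, "_rng_srna",
                                              np.random.default_rng(cfg.seed + 2))
    chroms: list[tuple[str, np.ndarray, np.ndarray]] = []
    for genome in ("A", "D"):
        for chrom in sorted(ds.genomes[genome]):
            L = len(ds.genomes[genome][chrom])
            w = np.full(L, cfg.srna_background_weight)
            for t in ds.pcg[genome]:
                if t.chrom != chrom:
                    continue
                s, e = t.interval.start, t.interval.end
                w[max(0, s - 1000):s] = cfg.srna_pcg_flank_weight
                w[e:e + 1000] = cfg.srna_pcg_flank_weight
                w[s:e] = cfg.srna_pcg_body_weight
            lnc_spans = [(t.interval.start, t.interval.end)
                         for t in ds.lnc[genome] if t.chrom == chrom]
            te_mask = np.zeros(L, dtype=bool)
            for te in ds.tes[genome]:
                if te.interval.chrom != chrom:
                    continue
                s, e = te.interval.start, te.interval.end
                inside_lnc = any(s < le and ls < e for ls, le in lnc_spans)
                weight = cfg.srna_te_body_weight * (
                    cfg.srna_lnc_te_depletion if inside_lnc else 1.0
                )
                w[s:e] = weight
                te_mask[s:e] = True
            chroms.append((chrom, w, te_mask))

    totals = np.array([w.sum() for _, w, _ in chroms])
    n_per_chrom = rng.multinomial(cfg.srna_n_reads, totals / totals.sum())
    reads = []
    for (chrom, w, te_mask), n_reads in zip(chroms, n_per_chrom):
        if n_reads == 0:
            continue
        cum = np.cumsum(w)
        starts = np.searchsorted(cum, rng.random(n_reads) * cum[-1])
        lengths = rng.integers(20, 26, size=n_reads)
        in_te = te_mask[np.minimum(starts, len(te_mask) - 1)]
        n_mapped = np.ones(n_reads, dtype=np.int64)
        n_mapped[in_te] += rng.poisson(2.0, size=int(in_te.sum()))
        heavy = rng.random(n_reads) < 0.02
        n_mapped[heavy & in_te] = rng.integers(
            40, 81, size=int((heavy & in_te).sum())
        )
        for s, l, nm in zip(starts, lengths, n_mapped):
            e = min(int(s) + int(l), len(w))
            if e - int(s) < 20:
                continue
            reads.append(
                SrnaRead(GenomicInterval(chrom, int(s), e, "+"), e - int(s),
                         int(nm))
            )
    return reads
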