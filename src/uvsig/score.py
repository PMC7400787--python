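"""Per-sample UV mutational-signature enrichment (UVMSE) scoring.

For every somatic SNV the 41-nt reference window centered on the variant is
extracted.  For each substitution channel m the context enrichment

    E_m = (Mut_m * Con_b) / (Mut_b * Con_m)

compares the fraction of the sample's mutations that fall in channel m
(``Mut_m`` of ``Mut_b``) with the availability of m's 3-base context motif in
the reference copies of the windows (``Con_m`` motif occurrences out of
``Con_b`` occurrences of the reference base).  Both numerator and denominator
fold the reverse complement: a GGA>GAA call counts as TCC>TTC, and motif /
base occurrences are counted on both strands.  The base class b of a channel
is its strand-folded substitution type (e.g. C>T): Mut_b counts the sample's
C>T plus G>A mutations and Con_b the C and G bases in the windows around
them.  The UVMSE score is the signature-probability-weighted sum of the
per-channel enrichments over all 192 strand-resolved channels.

Counts are pooled over all of a sample's windows before the ratio is taken
(the score is a per-sample statistic); overlapping windows are counted in
full; a degenerate denominator yields E_m = 0 (logged), which is the
conservative choice on short panels that may lack a motif entirely.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .tables import (
    BASES,
    PYRIMIDINES,
    MutationalSignature,
    SignatureChannel,
    classify_channel,
    reverse_complement,
)

log = logging.getLogger(__name__)

WINDOW_HALF_WIDTH = 20  # 41-nt windows
DEFAULT_MIN_QUAL = 50.0
DEFAULT_MIN_DEPTH = 100


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide substitution call (1-based coordinates)."""

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    depth: int | None = None
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")


@dataclass(frozen=True)
class ContextWindow:
    """Reference sequence around a variant, clipped at contig ends."""

    seq: str
    focal_offset: int

    @property
    def focal_base(self) -> str:
        return self.seq[self.focal_offset]


def _decompose(contig, pos, ref, alt, qual, depth, sample) -> list[VariantRecord]:
    """SNVs pass through; equal-length MNVs split per differing base;
    indels yield nothing (counted by the caller)."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != len(alt):
        return []
    return [
        VariantRecord(contig, pos + i, r, a, qual, depth, sample)
        for i, (r, a) in enumerate(zip(ref, alt))
        if r != a
    ]


def read_variants(
    path: str | Path,
    reference: str | Path | Fasta,
    sample: str | None = None,
) -> tuple[list[VariantRecord], dict]:
    """Read SNVs from a VCF (v4.x) or MAF file, verifying ref alleles.

    Multi-nucleotide substitutions (e.g. the UV-typical CC>TT tandem) are
    decomposed into their component SNVs; indels are dropped and counted.
    Returns the records plus a filter log with ``n_indels_dropped`` and
    ``n_ref_mismatch``.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    path = Path(path)
    raw: list[VariantRecord] = []
    n_indels = 0
    if path.suffix.lower() in {".maf", ".tsv", ".txt"}:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = {c.lower(): c for c in df.columns}

        def col(*names, required=True):
            for n in names:
                if n in cols:
                    return cols[n]
            if required:
                raise ValueError(f"MAF {path} lacks any of columns {names}")
            return None

        c_chrom = col("chromosome", "chrom", "contig")
        c_pos = col("start_position", "pos", "position")
        c_ref = col("reference_allele", "ref")
        c_alt = col("tumor_seq_allele2", "alt")
        c_sample = col("tumor_sample_barcode", "sample", required=False)
        for _, row in df.iterrows():
            ref, alt = str(row[c_ref]), str(row[c_alt])
            sid = sample or (str(row[c_sample]) if c_sample else "sample")
            if "-" in ref or "-" in alt or len(ref) != len(alt):
                n_indels += 1
                continue
            raw.extend(_decompose(str(row[c_chrom]), int(row[c_pos]), ref, alt, None, None, sid))
    else:
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        sample_id = sample or (vcf.samples[0] if vcf.samples else path.stem)
        for v in vcf:
            depth = v.INFO.get("DP")
            for alt in v.ALT:
                recs = _decompose(v.CHROM, v.POS, v.REF, alt, v.QUAL, depth, sample_id)
                if not recs and len(v.REF) != len(alt):
                    n_indels += 1
                raw.extend(recs)
    out, n_mismatch = [], 0
    for rec in raw:
        actual = str(fasta[rec.contig][rec.pos - 1 : rec.pos]).upper()
        if actual != rec.ref:
            n_mismatch += 1
            log.warning("ref mismatch at %s:%d (%s != %s); record rejected",
                        rec.contig, rec.pos, rec.ref, actual)
            continue
        out.append(rec)
    return out, {"n_indels_dropped": n_indels, "n_ref_mismatch": n_mismatch}


def _read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln} in {path}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {ln} in {path}") from exc
            intervals.setdefault(parts[0], []).append((start, end))
    return intervals


def filter_variants(
    records: list[VariantRecord],
    min_qual: float = DEFAULT_MIN_QUAL,
    min_depth: int = DEFAULT_MIN_DEPTH,
    regions: str | Path | None = None,
) -> list[VariantRecord]:
    """Drop low-quality calls and (optionally) calls outside BED regions.

    QUAL >= ``min_qual`` and depth >= ``min_depth`` are kept (calls below
    either threshold are excluded); records without a QUAL/depth annotation
    (e.g. from a MAF) pass those checks.  BED intervals are 0-based
    half-open.
    """
    bed = _read_bed(regions) if regions is not None else None
    out = []
    for rec in records:
        if rec.qual is not None and rec.qual < min_qual:
            continue
        if rec.depth is not None and rec.depth < min_depth:
            continue
        if bed is not None:
            hits = bed.get(rec.contig, ())
            if not any(start <= rec.pos - 1 < end for start, end in hits):
                continue
        out.append(rec)
    return out


def extract_window(
    reference: Fasta | str | Path,
    v: VariantRecord,
    half_width: int = WINDOW_HALF_WIDTH,
) -> ContextWindow:
    """Reference window pos-half_width .. pos+half_width, clipped to the
    contig; the focal base must equal the variant's ref allele."""
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    if v.contig not in fasta:
        raise KeyError(f"contig {v.contig!r} absent from reference")
    contig_len = len(fasta[v.contig])
    start = max(1, v.pos - half_width)
    end = min(contig_len, v.pos + half_width)
    seq = str(fasta[v.contig][start - 1 : end]).upper()
    win = ContextWindow(seq=seq, focal_offset=v.pos - start)
    if win.focal_base != v.ref:
        raise ValueError(
            f"window focal base {win.focal_base} != ref allele {v.ref} at {v.contig}:{v.pos}"
        )
    return win


_FOLD_TYPE = {  # substitution type -> strand-folded (pyrimidine-ref) type
    (r, a): ((r, a) if r in PYRIMIDINES else (reverse_complement(r), reverse_complement(a)))
    for r in BASES
    for a in BASES
    if r != a
}


@dataclass
class ChannelCounts:
    """Pooled mutation and context tallies feeding the enrichment ratio.

    Keys are strand-folded: channels by their pyrimidine-reference
    ``(ctx5, ref, alt, ctx3)`` tuple, classes by their pyrimidine-reference
    substitution type ``(ref, alt)``.
    """

    mut_channel: Counter = field(default_factory=Counter)
    mut_class: Counter = field(default_factory=Counter)
    motif_counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    base_counts: Counter = field(default_factory=Counter)
    n_variants: int = 0
    n_context_skipped: int = 0


def tally_channel_counts(
    variants: list[VariantRecord],
    windows: list[ContextWindow],
) -> ChannelCounts:
    """Count per-channel mutations and per-class context availability.

    Every variant contributes one ``Mut`` count, classified (folded) from
    the flanking bases of its own window; its window's reference copy
    contributes 3-mer motif counts and base counts to the variant's
    substitution class.  Variants whose window is clipped so hard that a
    flanking base is missing are skipped and counted.
    """
    if len(variants) != len(windows):
        raise ValueError("need exactly one window per variant")
    counts = ChannelCounts()
    for v, w in zip(variants, windows):
        i = w.focal_offset
        if i < 1 or i >= len(w.seq) - 1:
            counts.n_context_skipped += 1
            continue
        chan = classify_channel(v.ref, v.alt, w.seq[i - 1], w.seq[i + 1], fold_reverse_complement=True)
        t = _FOLD_TYPE[(v.ref, v.alt)]
        counts.mut_channel[chan.key] += 1
        counts.mut_class[t] += 1
        counts.n_variants += 1
        motifs = counts.motif_counts.setdefault(t, Counter())
        for j in range(len(w.seq) - 2):
            motifs[w.seq[j : j + 3]] += 1
        ref_base = t[0]
        comp = reverse_complement(ref_base)
        counts.base_counts[t] += w.seq.count(ref_base) + w.seq.count(comp)
    return counts


def channel_enrichment(
    counts: ChannelCounts, channel: SignatureChannel | tuple[str, str, str, str]
) -> float:
    """Context enrichment E_m = (Mut_m * Con_b) / (Mut_b * Con_m).

    Degenerate denominators (no mutations of the class, or the motif never
    occurring in the windows) yield 0.
    """
    key = channel.key if isinstance(channel, SignatureChannel) else tuple(channel)
    if key[1] not in PYRIMIDINES:
        key = classify_channel(key[1], key[2], key[0], key[3]).key
    t = (key[1], key[2])
    mut_m = counts.mut_channel.get(key, 0)
    mut_b = counts.mut_class.get(t, 0)
    motif = key[0] + key[1] + key[3]
    motifs = counts.motif_counts.get(t, Counter())
    con_m = motifs.get(motif, 0) + motifs.get(reverse_complement(motif), 0)
    con_b = counts.base_counts.get(t, 0)
    if mut_b == 0 or con_m == 0 or con_b == 0:
        if mut_m:
            log.debug("degenerate denominator for channel %s; E set to 0", "".join(key))
        return 0.0
    return (mut_m * con_b) / (mut_b * con_m)


@dataclass
class EnrichmentResult:
    """UVMSE score with its per-channel breakdown."""

    uvmse: float
    per_channel: pd.DataFrame  # ctx5 ref alt ctx3 p_m E_m weighted
    n_variants_used: int
    degenerate_channels: list[str]
    filter_log: dict = field(default_factory=dict)


def signature_enrichment(
    counts: ChannelCounts, signature: MutationalSignature
) -> EnrichmentResult:
    """UVMSE = sum over the 192 strand-resolved channels of p_m * E_m."""
    rows, degenerate = [], []
    for key, p in sorted(signature.probabilities.items()):
        e = channel_enrichment(counts, key)
        if e == 0.0 and p > 0:
            degenerate.append("".join(key))
        rows.append(
            {"ctx5": key[0], "ref": key[1], "alt": key[2], "ctx3": key[3],
             "p_m": p, "E_m": e, "weighted": p * e}
        )
    df = pd.DataFrame(rows)
    return EnrichmentResult(
        uvmse=float(df["weighted"].sum()),
        per_channel=df,
        n_variants_used=counts.n_variants,
        degenerate_channels=degenerate,
    )


def weighted_uv_load(n_mutations: int, uvmse: float) -> float:
    """UVMSE-weighted mutation load: total mutation count times the score."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return n_mutations * uvmse


def score_sample(
    variant_path: str | Path,
    reference: str | Path | Fasta,
    signature: MutationalSignature,
    regions: str | Path | None = None,
    min_qual: float = DEFAULT_MIN_QUAL,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample: str | None = None,
) -> EnrichmentResult:
    """End-to-end per-sample UVMSE: read, filter, window, tally, score."""
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    records, read_log = read_variants(variant_path, fasta, sample=sample)
    kept = filter_variants(records, min_qual=min_qual, min_depth=min_depth, regions=regions)
    windows = [extract_window(fasta, v) for v in kept]
    counts = tally_channel_counts(kept, windows)
    result = signature_enrichment(counts, signature)
    result.filter_log = dict(
        read_log, n_read=len(records), n_after_filter=len(kept),
        n_context_skipped=counts.n_context_skipped,
    )
    return result
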