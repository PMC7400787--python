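"""Seeded synthetic inputs with the statistical structure the methods assume.

Everything here is generative plumbing for testing and demonstration: a
random reference FASTA with controllable GC content, VCFs whose variant
contexts are drawn from a mutational signature at a controllable mixing
fraction ``f`` (vs a context-independent uniform background), a toy
transcriptome with expression levels, and a toy immunotherapy cohort with
a planted UV effect confined to the low/intermediate-TMB stratum.  All
outputs are deterministic functions of (parameters, seed) and round-trip
through the package's own readers.
"""

from __future__ import annotations

import itertools
import textwrap
from pathlib import Path

import numpy as np

from .tables import BASES, MutationalSignature, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def synth_reference(
    out_fasta: str | Path,
    length: int = 10_000,
    gc: float = 0.41,
    n_contigs: int = 1,
    seed: int = 0,
) -> Path:
    """Write a random reference FASTA with the requested GC fraction."""
    if length < 100:
        raise ValueError("length must be >= 100")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        for i in range(n_contigs):
            seq = "".join(rng.choice(list(BASES), size=length, p=p))
            fh.write(f">contig{i + 1}\n")
            fh.write("\n".join(textwrap.wrap(seq, 70)) + "\n")
    return out_fasta


def synth_variants(
    reference_seqs: dict[str, str],
    signature: MutationalSignature,
    n: int,
    f: float,
    seed: int = 0,
    out_vcf: str | Path | None = None,
    qual_range: tuple[float, float] = (60.0, 500.0),
    depth_range: tuple[int, int] = (120, 600),
) -> list[tuple[str, int, str, str, float, int]]:
    """Draw ``n`` SNVs; a fraction ``f`` from signature-matched contexts.

    With probability ``f`` a channel is drawn from the signature and the
    variant is placed (uniformly) at a reference position whose 3-mer
    context matches the channel's motif on either strand; otherwise a
    uniform random position gets a uniform random substitution.  QUAL and
    depth are sampled above the default filter thresholds.  Returns
    ``(contig, pos, ref, alt, qual, depth)`` tuples sorted by coordinate
    and optionally writes them as an uncompressed VCF.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    rng = _rng(seed)
    contigs = list(reference_seqs)
    # index interior positions by 3-mer motif
    motif_index: dict[str, list[tuple[str, int]]] = {}
    for c, seq in reference_seqs.items():
        seq = seq.upper()
        for i in range(1, len(seq) - 1):
            motif_index.setdefault(seq[i - 1 : i + 2], []).append((c, i + 1))  # 1-based
    channels = sorted(signature.probabilities)
    probs = np.array([signature.probabilities[c] for c in channels])
    probs = probs / probs.sum()
    taken: set[tuple[str, int]] = set()
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("reference too short to place the requested variants")
        if rng.random() < f:
            c5, ref, alt, c3 = channels[rng.choice(len(channels), p=probs)]
            # place on either strand
            if rng.random() < 0.5:
                motif, place_ref, place_alt = c5 + ref + c3, ref, alt
            else:
                motif = reverse_complement(c5 + ref + c3)
                place_ref, place_alt = reverse_complement(ref), reverse_complement(alt)
            sites = motif_index.get(motif)
            if not sites:
                continue  # motif absent: redraw
            contig, pos = sites[rng.integers(len(sites))]
        else:
            contig = contigs[rng.integers(len(contigs))]
            seq = reference_seqs[contig]
            pos = int(rng.integers(2, len(seq)))  # interior, 1-based
            place_ref = seq[pos - 1].upper()
            place_alt = rng.choice([b for b in BASES if b != place_ref])
        if (contig, pos) in taken:
            continue
        taken.add((contig, pos))
        qual = float(rng.uniform(*qual_range))
        depth = int(rng.integers(depth_range[0], depth_range[1]))
        out.append((contig, pos, place_ref, str(place_alt), round(qual, 1), depth))
    out.sort(key=lambda r: (r[0], r[1]))
    if out_vcf is not None:
        write_vcf(out, reference_seqs, out_vcf)
    return out


def write_vcf(
    records: list[tuple[str, int, str, str, float, int]],
    reference_seqs: dict[str, str],
    path: str | Path,
) -> Path:
    """Write SNV records as a minimal uncompressed VCF v4.2."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c, seq in reference_seqs.items():
            fh.write(f"##contig=<ID={c},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt, qual, depth in records:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\tDP={depth}\n")
    return path


def synth_transcriptome(
    n_transcripts: int = 20,
    mean_length_codons: int = 120,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Toy transcriptome: CDS FASTA, expression TSV, variant->CDS map.

    Each CDS starts with ATG, has no internal stop, and ends with a stop
    codon; expression is log-normal.  One random missense-capable SNV per
    transcript is emitted as the variant map.  Returns
    ``(transcripts, expression, variant_map)`` where ``variant_map`` rows
    are ``(transcript_id, cds_pos, ref, alt)``; files are written when
    ``out_dir`` is given.
    """
    rng = _rng(seed)
    sense_codons = sorted(
        "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS
    )
    transcripts, expression, variant_map = {}, {}, []
    for i in range(n_transcripts):
        tid = f"tx{i + 1}"
        n_codons = max(30, int(rng.poisson(mean_length_codons)))
        body = [sense_codons[j] for j in rng.integers(len(sense_codons), size=n_codons)]
        cds = "ATG" + "".join(body) + "TAA"
        transcripts[tid] = cds
        expression[tid] = float(np.round(rng.lognormal(mean=2.0, sigma=1.0), 4))
        # one random substitution in the body (positions after the start codon)
        pos = int(rng.integers(4, len(cds) - 3 + 1))
        ref = cds[pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        variant_map.append((tid, pos, ref, alt))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "cds.fasta", "w") as fh:
            for tid, cds in transcripts.items():
                fh.write(f">{tid}\n" + "\n".join(textwrap.wrap(cds, 70)) + "\n")
        with open(out_dir / "expression.tsv", "w") as fh:
            fh.write("transcript\texpression\n")
            for tid, e in expression.items():
                fh.write(f"{tid}\t{e}\n")
        with open(out_dir / "variant_map.tsv", "w") as fh:
            fh.write("transcript\tcds_pos\tref\talt\n")
            for tid, pos, ref, alt in variant_map:
                fh.write(f"{tid}\t{pos}\t{ref}\t{alt}\n")
    return transcripts, expression, variant_map


def synth_cohort(
    n: int = 120,
    seed: int = 0,
    uv_high_fraction: float = 0.3,
    response_prob: dict | None = None,
    pfs_scale_months: dict | None = None,
    censor_window_months: float = 48.0,
    out_tsv: str | Path | None = None,
):
    """Toy immunotherapy cohort with a planted UV effect.

    In the low/intermediate TMB stratum UV-high patients receive an
    elevated response probability and a longer exponential survival scale;
    in the high TMB stratum the UV groups are exchangeable.  Censoring is
    uniform over ``(0, censor_window_months]``.  Returns a DataFrame in the
    cohort-table dialect (and writes it when ``out_tsv`` is given).
    """
    import pandas as pd

    if n < 20:
        raise ValueError("cohort size must be >= 20")
    rng = _rng(seed)
    response_prob = response_prob or {
        ("low/intermediate", True): 0.45,
        ("low/intermediate", False): 0.14,
        ("high", True): 0.58,
        ("high", False): 0.57,
    }
    pfs_scale_months = pfs_scale_months or {
        ("low/intermediate", True): 12.0,
        ("low/intermediate", False): 4.0,
        ("high", True): 9.0,
        ("high", False): 9.0,
    }
    rows = []
    for i in range(n):
        uv_high = rng.random() < uv_high_fraction
        uvmse = rng.normal(0.95, 0.08) if uv_high else rng.normal(0.60, 0.08)
        # keep the score on the correct side of the default threshold
        uvmse = max(uvmse, 0.80) if uv_high else min(uvmse, 0.78)
        # median ~6 mut/Mb with ~10% of patients >= 20 (roughly the stated
        # 50/40/10 low/intermediate/high split of immunotherapy cohorts)
        tmb = float(np.round(rng.lognormal(1.8, 0.95), 1))
        stratum = "high" if tmb >= 20 else "low/intermediate"
        responder = rng.random() < response_prob[(stratum, uv_high)]
        response = ("CR" if rng.random() < 0.3 else "PR") if responder else (
            "SD" if rng.random() < 0.4 else "PD"
        )
        scale = pfs_scale_months[(stratum, uv_high)]
        pfs_t = rng.exponential(scale)
        os_t = pfs_t + rng.exponential(scale)
        censor = rng.uniform(0, censor_window_months)
        pfs, pfs_event = (pfs_t, 1) if pfs_t <= censor else (censor, 0)
        osm, os_event = (os_t, 1) if os_t <= censor else (censor, 0)
        rows.append(
            {
                "id": f"pt{i + 1}",
                "uvmse": round(float(uvmse), 4),
                "tmb": tmb,
                "response": response,
                "pfs_months": round(float(pfs), 2),
                "pfs_event": pfs_event,
                "os_months": round(float(osm), 2),
                "os_event": os_event,
            }
        )
    df = pd.DataFrame(rows)
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df
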