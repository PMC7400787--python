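"""Hydrophobicity change of mutated protein products and neopeptides.

Two per-mutation statistics are computed from a coding-sequence (CDS)
model and an SNV at a CDS coordinate:

* the **full-length delta**: total Kyte-Doolittle hydropathy of the mutated
  peptide minus that of the wild-type peptide;
* the **neopeptide delta**: the same difference summed over every 8-, 9-
  and 10-mer window that contains a mutated residue (the MHC class I
  presentation range).  An interior missense residue with at least nine
  flanking residues on both sides yields 8 + 9 + 10 = 27 window pairs.

Per-sample profiles sum these deltas over a tumor's mutations, optionally
weighting each transcript's contribution by its share of the sample's
total mRNA expression.  The profile is then correlated against the
UVMSE-weighted mutation load (ordinary least squares R-squared, Spearman
rank correlation and the slope's t-test p-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .tables import STOP_SYMBOL, HydropathyScale, hydropathy_sum

KMER_RANGE = (8, 9, 10)


@dataclass
class TranscriptModel:
    """An in-frame coding sequence with an optional expression level."""

    id: str
    cds: str
    expression: float | None = None
    partial: bool = False  # no start codon

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError(f"CDS length of {self.id} not divisible by 3")
        if self.expression is not None and self.expression < 0:
            raise ValueError("expression must be non-negative")
        if not self.cds.startswith("ATG"):
            self.partial = True

    def peptide(self) -> str:
        """Translation up to (excluding) the first stop codon."""
        pep = str(Seq(self.cds).translate())
        stop = pep.find(STOP_SYMBOL)
        return pep if stop == -1 else pep[:stop]


@dataclass
class MutatedTranscript:
    """A transcript with one applied variant, before/after peptides."""

    source_id: str
    cds_after: str
    peptide_before: str
    peptide_after: str
    changed_residues: tuple[int, ...]  # 0-based indices into peptide_before coords


@dataclass
class NeopeptidePair:
    before: str
    after: str
    k: int
    start: int  # 0-based residue index of the window


@dataclass
class NeopeptideSet:
    """All mutation-spanning k-mer windows of a mutated transcript."""

    pairs: list[NeopeptidePair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def mutate_transcript(t: TranscriptModel, cds_pos: int, ref: str, alt: str) -> MutatedTranscript:
    """Apply an SNV at 1-based CDS coordinate ``cds_pos``.

    Stop-gain truncates the mutant peptide; a stop-loss extends it to the
    next in-frame stop (or CDS end).  Changed residues are reported in the
    wild-type peptide's coordinates where comparable.
    """
    if not 1 <= cds_pos <= len(t.cds):
        raise ValueError(f"CDS position {cds_pos} outside {t.id} (len {len(t.cds)})")
    if t.cds[cds_pos - 1] != ref.upper():
        raise ValueError(
            f"ref allele {ref} does not match CDS base {t.cds[cds_pos - 1]} at {t.id}:{cds_pos}"
        )
    cds_after = t.cds[: cds_pos - 1] + alt.upper() + t.cds[cds_pos:]
    pep_before = t.peptide()
    pep_after = TranscriptModel(t.id, cds_after, t.expression).peptide()
    changed = tuple(
        i
        for i in range(max(len(pep_before), len(pep_after)))
        if (pep_before[i] if i < len(pep_before) else None)
        != (pep_after[i] if i < len(pep_after) else None)
    )
    return MutatedTranscript(
        source_id=t.id,
        cds_after=cds_after,
        peptide_before=pep_before,
        peptide_after=pep_after,
        changed_residues=changed,
    )


def full_length_delta(m: MutatedTranscript, scale: HydropathyScale) -> float:
    """Hydropathy(after peptide) - hydropathy(before peptide), in AU."""
    return hydropathy_sum(m.peptide_after, scale) - hydropathy_sum(m.peptide_before, scale)


def enumerate_neopeptides(m: MutatedTranscript, k_range: tuple[int, ...] = KMER_RANGE) -> NeopeptideSet:
    """All k-mer windows (k in ``k_range``) of the mutant peptide that
    contain a changed residue, paired with the same-coordinate wild-type
    window.  Window starts are clipped at the peptide termini; for a
    truncating variant the mutant-side window is itself clipped at the new
    terminus, so the pair's delta reflects the lost residues."""
    out = NeopeptideSet()
    if not m.changed_residues:
        return out
    n = max(len(m.peptide_after), len(m.peptide_before))
    for k in k_range:
        starts = set()
        for r in m.changed_residues:
            lo = max(0, r - k + 1)
            hi = min(r, n - k)
            starts.update(range(lo, hi + 1))
        for s in sorted(starts):
            out.pairs.append(
                NeopeptidePair(
                    before=m.peptide_before[s : s + k],
                    after=m.peptide_after[s : s + k],
                    k=k,
                    start=s,
                )
            )
    return out


def neopeptide_delta(
    nset: NeopeptideSet,
    scale: HydropathyScale,
    expression: float | None = None,
) -> float:
    """Sum over window pairs of hydropathy(after) - hydropathy(before), in
    AU; multiplied by the (normalized) expression level when given."""
    if expression is not None and expression < 0:
        raise ValueError("expression must be non-negative")
    total = sum(
        hydropathy_sum(p.after, scale) - hydropathy_sum(p.before, scale) for p in nset.pairs
    )
    return total * expression if expression is not None else total


def sample_hydrophobicity_profile(
    variants: list[tuple[str, int, str, str]],
    transcripts: dict[str, TranscriptModel],
    scale: HydropathyScale,
    mode: str = "neopeptide",
    weighted: bool = False,
) -> tuple[float, int]:
    """Total per-sample hydrophobicity change, in AU.

    ``variants`` is a list of ``(transcript_id, cds_pos, ref, alt)``.  In
    ``weighted`` mode each transcript's delta is multiplied by its fraction
    of the sample's total expression.  Returns ``(delta_au, n_unmapped)``;
    variants hitting unknown transcripts are logged, not fatal.
    """
    if mode not in {"full_length", "neopeptide"}:
        raise ValueError(f"unknown mode {mode!r}")
    total_expr = None
    if weighted:
        total_expr = sum(t.expression or 0.0 for t in transcripts.values())
        if total_expr <= 0:
            raise ValueError("expression weighting requested but total expression is 0")
    delta, n_unmapped = 0.0, 0
    for tid, pos, ref, alt in variants:
        t = transcripts.get(tid)
        if t is None:
            n_unmapped += 1
            continue
        m = mutate_transcript(t, pos, ref, alt)
        if mode == "full_length":
            d = full_length_delta(m, scale)
        else:
            d = neopeptide_delta(enumerate_neopeptides(m), scale)
        if weighted:
            d *= (t.expression or 0.0) / total_expr
        delta += d
    return delta, n_unmapped


@dataclass
class CorrelationReport:
    r_squared: float
    spearman_rho: float
    spearman_p: float
    slope: float
    slope_p: float
    n: int
    scatter: pd.DataFrame


def correlate_hydrophobicity_load(
    delta_au: np.ndarray | list[float],
    weighted_load: np.ndarray | list[float],
) -> CorrelationReport:
    """Linear fit of per-sample hydrophobicity change against the
    UVMSE-weighted mutation load, plus Spearman rank correlation.

    Requires at least three samples; zero variance in either variable is
    reported as NaN statistics rather than an error.
    """
    x = np.asarray(weighted_load, dtype=float)
    y = np.asarray(delta_au, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    scatter = pd.DataFrame({"weighted_load": x, "delta_au": y})
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return CorrelationReport(nan, nan, nan, nan, nan, x.size, scatter)
    fit = stats.linregress(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    return CorrelationReport(
        r_squared=float(fit.rvalue**2),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        slope=float(fit.slope),
        slope_p=float(fit.pvalue),
        n=int(x.size),
        scatter=scatter,
    )
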