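"""Constant reference tables and substitution-channel bookkeeping.

Three small tables underpin everything else in this package:

* a **mutational signature**: a probability distribution over the 192
  strand-resolved single-base substitution channels (a substitution
  ``ref->alt`` together with its immediate 5' and 3' flanking bases);
* a **codon usage table**: the frequency of each of the 64 codons in the
  coding genome, used as the prior over hexanucleotide stretches;
* a **hydropathy scale**: the Kyte-Doolittle per-residue hydrophobicity
  index, in arbitrary units (AU).

Default copies of all three ship with the package (see :func:`bundled_path`);
any of them can be replaced by a user-supplied TSV in the same dialect.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

STOP_SYMBOL = "*"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: (ctx5, ref, alt, ctx3) tuples for all 192 strand-resolved channels.
ALL_CHANNELS = tuple(
    (c5, ref, alt, c3)
    for c5 in BASES
    for ref in BASES
    for alt in BASES
    for c3 in BASES
    if ref != alt
)

#: The 96 channels with a pyrimidine reference base (the canonical half
#: after reverse-complement folding).
PYRIMIDINE_CHANNELS = tuple(c for c in ALL_CHANNELS if c[1] in PYRIMIDINES)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_channel(channel: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    """The same substitution read off the opposite strand."""
    c5, ref, alt, c3 = channel
    return (
        reverse_complement(c3),
        reverse_complement(ref),
        reverse_complement(alt),
        reverse_complement(c5),
    )


class TableError(ValueError):
    """Raised when a reference table fails validation."""


@dataclass(frozen=True)
class SignatureChannel:
    """A canonical substitution channel key, optionally strand-folded."""

    ctx5: str
    ref: str
    alt: str
    ctx3: str
    folded: bool = False

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.ctx5, self.ref, self.alt, self.ctx3)

    @property
    def motif(self) -> str:
        """The 3-base reference context motif of this channel."""
        return self.ctx5 + self.ref + self.ctx3

    def __str__(self) -> str:  # e.g. "TCC>TTC"
        return f"{self.motif}>{self.ctx5}{self.alt}{self.ctx3}"


def classify_channel(
    ref: str,
    alt: str,
    ctx5: str,
    ctx3: str,
    fold_reverse_complement: bool = True,
) -> SignatureChannel:
    """Classify a single-base substitution into its signature channel.

    With ``fold_reverse_complement`` on, a purine-reference substitution is
    mapped to the equivalent channel on the opposite strand, so every
    channel key has a pyrimidine (C or T) reference base; substitutions on
    the two strands are then counted identically.
    """
    for b, name in ((ref, "ref"), (alt, "alt"), (ctx5, "ctx5"), (ctx3, "ctx3")):
        if b not in BASES:
            raise TableError(f"non-ACGT {name} base {b!r}")
    if ref == alt:
        raise TableError(f"ref equals alt ({ref!r})")
    key = (ctx5, ref, alt, ctx3)
    if fold_reverse_complement and ref not in PYRIMIDINES:
        key = complement_channel(key)
    return SignatureChannel(*key, folded=fold_reverse_complement)


@dataclass
class MutationalSignature:
    """Probability distribution over substitution channels.

    ``probabilities`` maps the 192 strand-resolved ``(ctx5, ref, alt, ctx3)``
    keys to fractions summing to one.  A 96-channel strand-folded table is
    accepted at load time and symmetrized with halved mass per strand.
    """

    probabilities: dict[tuple[str, str, str, str], float]
    name: str = "signature"
    strand_resolved: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in ALL_CHANNELS if c not in self.probabilities]
        if missing:
            raise TableError(
                f"signature {self.name!r} is missing channel "
                f"{''.join(missing[0])} ({len(missing)} absent in total)"
            )
        extra = set(self.probabilities) - set(ALL_CHANNELS)
        if extra:
            raise TableError(f"signature {self.name!r} has invalid channel keys: {sorted(extra)[:3]}")
        for chan, p in self.probabilities.items():
            if p < 0:
                raise TableError(f"negative probability for channel {''.join(chan)}: {p}")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-6:
            raise TableError(f"signature {self.name!r} probabilities sum to {total!r}, not 1")

    def probability(self, channel: SignatureChannel | tuple[str, str, str, str]) -> float:
        key = channel.key if isinstance(channel, SignatureChannel) else tuple(channel)
        return self.probabilities[key]

    def folded(self) -> dict[tuple[str, str, str, str], float]:
        """Per-pyrimidine-channel mass with the reciprocal strand folded in."""
        return {
            c: self.probabilities[c] + self.probabilities[complement_channel(c)]
            for c in PYRIMIDINE_CHANNELS
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ctx5\tref\talt\tctx3\tprob\n")
            for chan in sorted(self.probabilities):
                fh.write("%s\t%s\t%s\t%s\t%.17g\n" % (chan + (self.probabilities[chan],)))


@dataclass
class CodonUsageTable:
    """Fraction of coding-genome codons for each of the 64 codons."""

    frequencies: dict[str, float]

    ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))

    def __post_init__(self) -> None:
        missing = [c for c in self.ALL_CODONS if c not in self.frequencies]
        if missing:
            raise TableError(f"codon table missing {missing[0]} ({len(missing)} absent)")
        for codon, f in self.frequencies.items():
            if f < 0:
                raise TableError(f"negative frequency for codon {codon}: {f}")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-4:
            raise TableError(f"codon frequencies sum to {total!r}, not 1")

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[codon]

    def nucleotide_marginal(self) -> dict[str, float]:
        """Per-base frequency implied by the codon usage (averaged over the
        three codon positions)."""
        marg = dict.fromkeys(BASES, 0.0)
        for codon, f in self.frequencies.items():
            for b in codon:
                marg[b] += f / 3.0
        return marg

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tfreq\n")
            for codon in self.ALL_CODONS:
                fh.write("%s\t%.17g\n" % (codon, self.frequencies[codon]))


@dataclass
class HydropathyScale:
    """Per-residue hydropathy index in AU; stop codons get a configurable
    constant (default 0 AU -- stop gain is tracked as a census, not as
    hydropathy)."""

    index: dict[str, float]
    stop_value: float = 0.0

    def __post_init__(self) -> None:
        missing = [a for a in AA_ALPHABET if a not in self.index]
        if missing:
            raise TableError(f"hydropathy scale missing residues {missing}")

    def __getitem__(self, residue: str) -> float:
        if residue == STOP_SYMBOL:
            return self.stop_value
        try:
            return self.index[residue]
        except KeyError:
            raise TableError(f"unknown residue symbol {residue!r}") from None


def hydropathy_sum(peptide: str, scale: HydropathyScale) -> float:
    """Total hydropathy of a peptide, in AU (empty peptide -> 0 AU)."""
    return sum(scale[a] for a in peptide)


# ---------------------------------------------------------------------------
# loading

def bundled_path(name: str) -> Path:
    """Path to a bundled data file (``signature``, ``codon_usage``, ``scale``)."""
    files = {
        "signature": "uv_signature_synthetic.tsv",
        "codon_usage": "kazusa_human_codon_usage.tsv",
        "scale": "kyte_doolittle.tsv",
    }
    return Path(str(resources.files("uvsig") / "data" / files[name]))


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def load_signature(
    path: str | Path | None = None,
    strand_resolved: bool = True,
    name: str | None = None,
) -> MutationalSignature:
    """Load a signature TSV with columns ``ctx5 ref alt ctx3 prob``.

    A 96-row pyrimidine-reference table is accepted when
    ``strand_resolved=False`` (or detected from the row count) and is
    symmetrized: each channel's mass is split evenly between the two strands.
    """
    if path is None:
        path = bundled_path("signature")
        name = name or "uv-synthetic"
    df = _read_tsv(path)
    required = ["ctx5", "ref", "alt", "ctx3", "prob"]
    if not set(required) <= set(df.columns):
        raise TableError(f"signature file {path} must have columns {required}")
    probs: dict[tuple[str, str, str, str], float] = {}
    for row in df.itertuples(index=False):
        key = (row.ctx5.upper(), row.ref.upper(), row.alt.upper(), row.ctx3.upper())
        if key in probs:
            raise TableError(f"duplicate channel {''.join(key)} in {path}")
        probs[key] = float(row.prob)
    if len(probs) == 96 and all(k[1] in PYRIMIDINES for k in probs):
        warnings.warn(
            "96-channel strand-folded signature: symmetrizing with halved mass per strand",
            stacklevel=2,
        )
        probs = {
            k: p
            for c, half in ((c, probs[c] / 2.0) for c in list(probs))
            for k, p in ((c, half), (complement_channel(c), half))
        }
        strand_resolved = False
    sig = MutationalSignature(probs, name=name or Path(path).stem, strand_resolved=strand_resolved)
    return sig


def load_codon_usage(path: str | Path | None = None) -> CodonUsageTable:
    """Load a 64-row codon usage TSV (``codon`` plus one numeric column).

    Inputs in per-1000 (or any other consistent) units are rescaled by the
    column total so frequencies sum to one.
    """
    if path is None:
        path = bundled_path("codon_usage")
    df = _read_tsv(path)
    if "codon" not in df.columns or len(df.columns) < 2:
        raise TableError(f"codon usage file {path} needs a 'codon' column plus a value column")
    value_col = [c for c in df.columns if c != "codon"][0]
    raw = {str(r.codon).upper().replace("U", "T"): float(getattr(r, value_col)) for r in df.itertuples(index=False)}
    total = sum(raw.values())
    if total <= 0:
        raise TableError("codon usage totals zero")
    return CodonUsageTable({c: v / total for c, v in raw.items()})


def load_hydropathy_scale(path: str | Path | None = None, stop_value: float = 0.0) -> HydropathyScale:
    """Load a 20-row per-residue hydropathy TSV (``residue`` ``index``)."""
    if path is None:
        path = bundled_path("scale")
    df = _read_tsv(path)
    if not {"residue", "index"} <= set(df.columns):
        raise TableError(f"hydropathy file {path} must have columns ['residue', 'index']")
    return HydropathyScale(
        {str(r.residue).upper(): float(r.index) for r in df.itertuples(index=False)},
        stop_value=stop_value,
    )
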