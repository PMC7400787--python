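"""Iterative in-silico UV mutagenesis over short coding stretches.

The coding genome is abstracted as the set of all 6-nucleotide stretches
(two adjacent codons; 4^6 = 4096 of them), each carrying a probability mass
equal to the product of its two codon-usage frequencies.  One iteration of
mutagenesis applies the signature to every mutable position of every
stretch: for each single-base substitution the signature probability of the
corresponding channel acts as a per-opportunity transition rate, moving
that share of the stretch's mass onto the singly-mutated stretch.  Only
positions 2-5 are mutable -- positions 1 and 6 lack a flanking base inside
the stretch, so their channel is undefined.  Mass not selected for any
mutation stays put, making the update a proper (mass-conserving) Markov
chain whose state is the distribution over the 4096 stretches.

Each iteration plays the role of a unit dose of UV exposure; repeated
iterations model cumulative exposure.  The observables reported per
iteration are the exome-wide expected hydropathy (mass-weighted
Kyte-Doolittle AU of the encoded dipeptides), the per-residue amino-acid
census, and the stop-codon mass relative to the unmutated baseline.

A reduced 5-nucleotide mode (one codon flanked by one context base on each
side, mutable positions 2-4) is available as a robustness check; flanking
bases there are given the nucleotide marginal implied by the codon usage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import sparse
from scipy.stats import wilcoxon

from .tables import (
    BASES,
    STOP_SYMBOL,
    CodonUsageTable,
    HydropathyScale,
    MutationalSignature,
    complement_channel,
    hydropathy_sum,
)

STOP_CODONS = ("TAA", "TAG", "TGA")

_CODON_TO_AA = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product(BASES, repeat=3)
}


def translate_codon(codon: str) -> str:
    """Standard-code translation of one codon; stop -> ``*``."""
    return _CODON_TO_AA[codon]


def all_stretches(length: int = 6) -> list[str]:
    """All 4^length nucleotide stretches, in lexicographic order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=length)]


def _codon_starts(length: int) -> tuple[int, ...]:
    if length == 6:
        return (0, 3)
    if length == 5:
        return (1,)
    raise ValueError("stretch length must be 5 or 6")


def stretch_hydropathy(stretch: str, scale: HydropathyScale) -> float:
    """AU of the peptide encoded by the in-frame codons of a stretch."""
    peptide = "".join(translate_codon(stretch[i : i + 3]) for i in _codon_starts(len(stretch)))
    return hydropathy_sum(peptide, scale)


@dataclass
class StretchDistribution:
    """Probability mass over the 4^length stretches, plus iteration count."""

    stretches: list[str]
    mass: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if (self.mass < -1e-15).any():
            raise ValueError("negative stretch mass")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"stretch masses sum to {self.mass.sum()!r}, not 1")

    def __getitem__(self, stretch: str) -> float:
        return float(self.mass[self.stretches.index(stretch)])


def enumerate_and_initialize(
    codon_usage: CodonUsageTable, length: int = 6
) -> StretchDistribution:
    """Initial distribution: mass(s) = product of codon-usage priors.

    For 6-nt stretches this is P(codon1) * P(codon2); in the reduced 5-nt
    mode the single codon prior is multiplied by the nucleotide marginal of
    each flanking base.
    """
    stretches = all_stretches(length)
    starts = _codon_starts(length)
    marg = codon_usage.nucleotide_marginal()
    flanks = [i for i in range(length) if not any(s <= i < s + 3 for s in starts)]
    mass = np.empty(len(stretches))
    for i, s in enumerate(stretches):
        m = 1.0
        for st in starts:
            m *= codon_usage[s[st : st + 3]]
        for f in flanks:
            m *= marg[s[f]]
        mass[i] = m
    mass /= mass.sum()  # flank marginals already sum to 1; guards rounding
    return StretchDistribution(stretches, mass)


def enumerate_single_mutants(length: int = 6) -> list[tuple[str, int, str, str]]:
    """All (stretch, position, alt, mutant) single-substitution records.

    Positions are 1-based; only positions with both flanking bases inside
    the stretch are mutable (2..length-1), giving 4^length * (length-2) * 3
    records -- 49 152 for the 6-nt stretches.
    """
    out = []
    for s in all_stretches(length):
        for pos in range(2, length):  # 1-based positions 2..length-1
            ref = s[pos - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                out.append((s, pos, alt, s[: pos - 1] + alt + s[pos:]))
    return out


def mutation_probability(
    stretch: str,
    position: int,
    alt: str,
    signature: MutationalSignature,
    include_reciprocal: bool = False,
) -> float:
    """Signature probability of substituting ``alt`` at a 1-based position.

    The channel is read directly off the written strand (the signature is
    strand-resolved).  With ``include_reciprocal`` the complement-strand
    channel's probability is credited as well, modelling mutagenesis hitting
    either strand.
    """
    if not 2 <= position <= len(stretch) - 1:
        raise ValueError(f"position {position} has no flanking context in a {len(stretch)}-mer")
    key = (stretch[position - 2], stretch[position - 1], alt, stretch[position])
    q = signature.probabilities.get(key)
    if q is None:  # pragma: no cover - all 192 keys exist in a valid signature
        return 0.0
    if include_reciprocal:
        q = q + signature.probabilities.get(complement_channel(key), 0.0)
    return q


def _transition_matrix(
    stretches: list[str],
    signature: MutationalSignature,
    include_reciprocal: bool,
) -> sparse.csr_matrix:
    """Column-stochastic-defective matrix T with T[dst, src] = q(src->dst)."""
    index = {s: i for i, s in enumerate(stretches)}
    length = len(stretches[0])
    rows, cols, vals = [], [], []
    outflow = np.zeros(len(stretches))
    for src, pos, alt, dst in enumerate_single_mutants(length):
        q = mutation_probability(src, pos, alt, signature, include_reciprocal)
        if q == 0.0:
            continue
        i, j = index[src], index[dst]
        rows.append(j)
        cols.append(i)
        vals.append(q)
        outflow[i] += q
    if (outflow > 1.0 + 1e-12).any():
        worst = stretches[int(outflow.argmax())]
        raise ValueError(
            f"signature rates are not interpretable as per-opportunity "
            f"probabilities: outgoing rate {outflow.max():.4f} > 1 for stretch {worst}"
        )
    n = len(stretches)
    T = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    T += sparse.diags(1.0 - outflow)
    return T


def apply_iteration(
    dist: StretchDistribution,
    signature: MutationalSignature,
    scale: HydropathyScale | None = None,
    include_reciprocal: bool = False,
    _T: sparse.csr_matrix | None = None,
) -> tuple[StretchDistribution, float]:
    """One mutagenesis cycle; returns the new distribution and the expected
    hydropathy change sum_s sum_m p(s) q(s->m) (AU(m) - AU(s))."""
    T = _T if _T is not None else _transition_matrix(dist.stretches, signature, include_reciprocal)
    new_mass = T @ dist.mass
    delta = 0.0
    if scale is not None:
        au = np.array([stretch_hydropathy(s, scale) for s in dist.stretches])
        delta = float(au @ new_mass - au @ dist.mass)
    return StretchDistribution(dist.stretches, new_mass, dist.iteration + 1), delta


def amino_acid_census(dist: StretchDistribution) -> pd.DataFrame:
    """Mass-weighted residue frequencies (20 residues + stop) per codon slot.

    Returns a DataFrame indexed by residue with one column per codon slot
    plus a ``mean`` column; each slot column sums to 1.  Multiply by 4096 for
    a pseudo-count census.
    """
    starts = _codon_starts(len(dist.stretches[0]))
    residues = sorted(set(_CODON_TO_AA.values()))
    freq = pd.DataFrame(0.0, index=residues, columns=[f"slot{k + 1}" for k in range(len(starts))])
    for s, m in zip(dist.stretches, dist.mass):
        for k, st in enumerate(starts):
            freq.loc[translate_codon(s[st : st + 3]), f"slot{k + 1}"] += m
    freq["mean"] = freq[[c for c in freq.columns]].mean(axis=1)
    return freq


def stop_codon_mass(dist: StretchDistribution) -> float:
    """Expected number of stop codons per stretch (summed over codon slots)."""
    starts = _codon_starts(len(dist.stretches[0]))
    total = 0.0
    for s, m in zip(dist.stretches, dist.mass):
        total += m * sum(s[st : st + 3] in STOP_CODONS for st in starts)
    return total


@dataclass
class MutagenesisReport:
    """Per-iteration trajectory of the simulated exome."""

    per_iteration: pd.DataFrame  # iteration, hydropathy, delta, stop_mass, stop_gain_pct
    census: dict[int, pd.DataFrame]  # iteration -> amino_acid_census
    final: StretchDistribution
    include_reciprocal: bool
    per_stretch: pd.DataFrame | None = None  # iteration-1 before/after AU-weighted values

    def wilcoxon_before_after(self) -> tuple[float, float]:
        """Wilcoxon signed-rank test on the per-stretch AU-weighted values
        before vs after the first iteration."""
        if self.per_stretch is None:
            raise ValueError("report was built without a per-stretch table")
        stat, p = wilcoxon(self.per_stretch["after"], self.per_stretch["before"])
        return float(stat), float(p)


def run_simulation(
    n_iterations: int,
    codon_usage: CodonUsageTable,
    signature: MutationalSignature,
    scale: HydropathyScale,
    include_reciprocal: bool = False,
    length: int = 6,
    census_at: tuple[int, ...] = (0,),
    per_stretch_table: bool = False,
) -> MutagenesisReport:
    """Run ``n_iterations`` deterministic mutagenesis cycles.

    Row 0 of the per-iteration table is the unmutated baseline.  ``census_at``
    selects the iterations at which a full amino-acid census is recorded
    (the final iteration is always included).
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    dist = enumerate_and_initialize(codon_usage, length)
    au = np.array([stretch_hydropathy(s, scale) for s in dist.stretches])
    T = _transition_matrix(dist.stretches, signature, include_reciprocal)

    stop0 = stop_codon_mass(dist)
    rows = [
        {
            "iteration": 0,
            "hydropathy_au": float(au @ dist.mass),
            "delta_au": 0.0,
            "stop_mass": stop0,
            "stop_gain_pct": 0.0,
        }
    ]
    census = {}
    wanted = set(census_at) | {n_iterations}
    if 0 in wanted:
        census[0] = amino_acid_census(dist)
    per_stretch = None
    for it in range(1, n_iterations + 1):
        before = dist
        dist, delta = apply_iteration(dist, signature, scale, include_reciprocal, _T=T)
        if it == 1 and per_stretch_table:
            # per-stretch AU-weighted value: p0(s)*AU(s) before, and after the
            # transition the same mass redistributed over s and its mutants
            after_vals = before.mass * np.asarray(
                T.multiply(au[:, None]).sum(axis=0)
            ).ravel()
            per_stretch = pd.DataFrame(
                {
                    "stretch": dist.stretches,
                    "before": before.mass * au,
                    "after": after_vals,
                }
            )
        stop = stop_codon_mass(dist)
        rows.append(
            {
                "iteration": it,
                "hydropathy_au": float(au @ dist.mass),
                "delta_au": delta,
                "stop_mass": stop,
                "stop_gain_pct": 100.0 * (stop - stop0) / stop0 if stop0 > 0 else float("nan"),
            }
        )
        if it in wanted:
            census[it] = amino_acid_census(dist)
    return MutagenesisReport(
        per_iteration=pd.DataFrame(rows),
        census=census,
        final=dist,
        include_reciprocal=include_reciprocal,
        per_stretch=per_stretch,
    )
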