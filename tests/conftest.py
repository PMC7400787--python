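import pytest
from pyfaidx import Fasta

from uvsig.synth import synth_reference, synth_variants
from uvsig.tables import (
    ALL_CHANNELS,
    MutationalSignature,
    load_codon_usage,
    load_hydropathy_scale,
    load_signature,
)


@pytest.fixture(scope="session")
def signature():
    return load_signature()


@pytest.fixture(scope="session")
def codon_usage():
    return load_codon_usage()


@pytest.fixture(scope="session")
def scale():
    return load_hydropathy_scale()


@pytest.fixture(scope="session")
def uniform_signature():
    return MutationalSignature(
        {c: 1.0 / len(ALL_CHANNELS) for c in ALL_CHANNELS}, name="uniform"
    )


@pytest.fixture(scope="session")
def toy_two_channel_signature():
    """Mass concentrated on TCC>TTC (0.3) and its reciprocal GGA>GAA (0.2);
    the remainder spread uniformly over the other 190 channels.  Keeps every
    per-stretch outgoing rate below 1 (a stretch can host two copies of the
    same motif)."""
    rest = 0.5 / 190
    probs = dict.fromkeys(ALL_CHANNELS, rest)
    probs[("T", "C", "T", "C")] = 0.3
    probs[("G", "G", "A", "A")] = 0.2
    return MutationalSignature(probs, name="toy")


@pytest.fixture(scope="session")
def reference(tmp_path_factory):
    """20 kb single-contig synthetic reference (GC 0.41, seed 1)."""
    path = tmp_path_factory.mktemp("ref") / "reference.fasta"
    synth_reference(path, length=20_000, gc=0.41, seed=1)
    return path


@pytest.fixture(scope="session")
def reference_fasta(reference):
    return Fasta(str(reference))


@pytest.fixture(scope="session")
def reference_seqs(reference_fasta):
    return {k: str(v) for k, v in reference_fasta.items()}


@pytest.fixture()
def make_vcf(tmp_path, reference_seqs, signature):
    """Factory writing a synthetic VCF for a given (n, f, seed)."""

    def _make(n=100, f=0.5, seed=0, name="sample.vcf", **kw):
        path = tmp_path / name
        synth_variants(reference_seqs, signature, n=n, f=f, seed=seed, out_vcf=path, **kw)
        return path

    return _make
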