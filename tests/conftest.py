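import numpy as np
import pytest

from mmejsig.genome import GenomeSequence
from mmejsig.variants import IndelRecord, IndelSet


@pytest.fixture
def toy_genome():
    return GenomeSequence({"c1": "AAACGTTT", "c2": "GCATATATG"})


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_record(contig="c1", pos=1, ref="A", alt="AG", qual=60.0):
    return IndelRecord(contig, pos, ref, alt, qual)


def random_genome(rng, length=2000, name="chr1"):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length).tobytes().decode()
    return GenomeSequence({name: seq})


def write_vcf_text(path, rows, contigs=(("c1", 100),)):
    """Write a minimal VCF from (chrom, pos, ref, alt, qual) tuples; qual may
    be None for a missing value."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alt, qual in rows:
        q = "." if qual is None else f"{qual:g}"
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{q}\t.\t.")
    path.write_text("\n".join(lines) + "\n")
    return path
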