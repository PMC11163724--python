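import numpy as np
import pytest

from skiptics.junction_io import ExonRecord, SpliceJunction


@pytest.fixture
def make_exon():
    def _make(
        start,
        end,
        strand="+",
        chrom="chr1",
        exon_id="e1",
        gene_id="g1",
        transcript_id="t1",
    ):
        return ExonRecord(
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            gene_id=gene_id,
            exon_id=exon_id,
            transcript_id=transcript_id,
        )

    return _make


@pytest.fixture
def make_junction():
    def _make(start, end, strand="+", reads=10, chrom="chr1", sample_id="s1"):
        return SpliceJunction(
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            reads=reads,
            sample_id=sample_id,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240609)
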