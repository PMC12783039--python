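"""Shared fixtures: tiny sequences, HSP builders and simulated loci."""

from __future__ import annotations

import pytest

from tastkit import HspRecord, LocusSpec, SequenceRecord, simulate_locus


def make_hsp(
    q_start,
    q_end,
    s_start,
    s_end,
    query_id="tx1",
    subject_id="g1",
    strand="forward",
    percent_identity=100.0,
    bitscore=None,
    e_value=0.0,
):
    """HSP with sensible defaults; bitscore defaults to the query span."""
    return HspRecord(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        strand=strand,
        percent_identity=percent_identity,
        align_length=max(q_end - q_start, 1),
        bitscore=float(q_end - q_start) if bitscore is None else float(bitscore),
        e_value=e_value,
    )


@pytest.fixture
def hsp_factory():
    return make_hsp


@pytest.fixture(scope="session")
def default_locus():
    """One deterministic four-exon locus with the short leading exons."""
    return simulate_locus(LocusSpec(seed=1))


@pytest.fixture
def seq_factory():
    def _make(residues, id="s1", description=""):
        return SequenceRecord(id, residues, description)

    return _make
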