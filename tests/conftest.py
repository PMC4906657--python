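"""Shared fixtures and alignment-record builders for the test suite."""

from __future__ import annotations

import sys
from pathlib import Path
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sparsecons.io_formats import M5Record, SequenceRecord


def perfect_m5(
    qname: str,
    target: SequenceRecord,
    tstart: int,
    tend: int,
    score: int = -100,
) -> M5Record:
    """An error-free alignment of target[tstart:tend] against itself."""
    segment = target.sequence[tstart:tend]
    return M5Record(
        qName=qname,
        qLength=len(segment),
        qStart=0,
        qEnd=len(segment),
        qStrand="+",
        tName=target.name,
        tLength=len(target.sequence),
        tStart=tstart,
        tEnd=tend,
        tStrand="+",
        score=score,
        numMatch=len(segment),
        numMismatch=0,
        numIns=0,
        numDel=0,
        mapQV=254,
        qAlignedSeq=segment,
        matchPattern="|" * len(segment),
        tAlignedSeq=segment,
    )


def gapped_m5(
    qname: str,
    target: SequenceRecord,
    tstart: int,
    q_aln: str,
    t_aln: str,
) -> M5Record:
    """Build a record from explicit gapped strings (handcrafted variants)."""
    assert len(q_aln) == len(t_aln)
    q_len = len(q_aln.replace("-", ""))
    t_len = len(t_aln.replace("-", ""))
    pattern = "".join(
        "|" if a == b and a != "-" else "*" for a, b in zip(q_aln, t_aln)
    )
    rec = M5Record(
        qName=qname,
        qLength=q_len,
        qStart=0,
        qEnd=q_len,
        qStrand="+",
        tName=target.name,
        tLength=len(target.sequence),
        tStart=tstart,
        tEnd=tstart + t_len,
        tStrand="+",
        score=-pattern.count("|"),
        numMatch=pattern.count("|"),
        numMismatch=sum(
            1 for a, b in zip(q_aln, t_aln) if a != "-" and b != "-" and a != b
        ),
        numIns=t_aln.count("-"),
        numDel=q_aln.count("-"),
        mapQV=254,
        qAlignedSeq=q_aln,
        matchPattern=pattern,
        tAlignedSeq=t_aln,
    )
    rec.validate(where=f"test:{qname}")
    return rec


@pytest.fixture
def small_backbone() -> SequenceRecord:
    return SequenceRecord(name="bb", sequence="ACGTACGGTACT")
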