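"""Derive statistic inputs (n, m, theta-pi) from an aligned sample.

An *allele* is a distinct full-length sequence (haplotype) in the aligned
sample; ``m`` counts them. The diversity estimate theta-pi is the average
pairwise nucleotide difference

    theta_pi = 2 / (n (n + 1)) * sum_{i<j} dist(D_i, D_j)

("paper" denominator convention; the conventional mean over the C(n, 2)
pairs uses ``n (n - 1)`` and is selectable as convention="tajima" — see the
methods note). ``dist`` counts positions at which two sequences differ;
under the default pairwise-deletion policy, columns where either sequence
carries a non-ACGT character (gaps, Ns, ambiguity codes) are skipped for
that pair, while the strict policy treats any non-ACGT character as an
error. Sequences are uppercased and U is read as T before any comparison;
allele identity is plain string identity of the normalized sequences, so
gap characters do participate in distinguishing alleles.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .params import AlignmentSummary

__all__ = [
    "pairwise_dist",
    "summarize_alignment",
    "read_fasta",
    "summarize_fasta",
]

_ACGT = frozenset(b"ACGT")


def _normalize(seq: str) -> bytes:
    return seq.upper().replace("U", "T").encode("ascii")


def pairwise_dist(a: str, b: str, policy: str = "pairwise-deletion") -> int:
    """Number of positions at which two aligned sequences differ.

    Symmetric, zero on identical input. Under ``pairwise-deletion``,
    positions where either character is outside {A, C, G, T} are skipped;
    under ``strict`` any such character raises.
    """
    if len(a) != len(b):
        raise ValueError(
            f"aligned sequences must have equal length, got {len(a)} and {len(b)}"
        )
    ab = np.frombuffer(_normalize(a), dtype=np.uint8)
    bb = np.frombuffer(_normalize(b), dtype=np.uint8)
    valid_a = np.isin(ab, np.frombuffer(b"ACGT", dtype=np.uint8))
    valid_b = np.isin(bb, np.frombuffer(b"ACGT", dtype=np.uint8))
    if policy == "strict":
        if not valid_a.all() or not valid_b.all():
            raise ValueError("non-ACGT character under strict comparison policy")
        return int(np.count_nonzero(ab != bb))
    if policy == "pairwise-deletion":
        keep = valid_a & valid_b
        return int(np.count_nonzero((ab != bb) & keep))
    raise ValueError(f"unknown comparison policy {policy!r}")


def summarize_alignment(
    records: Iterable[Tuple[str, str]],
    convention: str = "paper",
    policy: str = "pairwise-deletion",
) -> AlignmentSummary:
    """(n, L, m, theta_pi) for a list of ``(id, sequence)`` pairs.

    ``m`` is the number of distinct normalized sequences. Duplicate record
    IDs warn; unequal sequence lengths raise.
    """
    if convention not in ("paper", "tajima"):
        raise ValueError(f"unknown denominator convention {convention!r}")
    recs = list(records)
    if len(recs) < 2:
        raise ValueError(f"need at least 2 sequences, got {len(recs)}")
    ids = [r[0] for r in recs]
    if len(set(ids)) != len(ids):
        warnings.warn("duplicate sequence IDs in alignment", stacklevel=2)
    seqs = [_normalize(r[1]) for r in recs]
    L = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(
                f"sequence {ids[i]!r} has length {len(s)}, expected {L}"
            )
    n = len(seqs)
    m = len(set(seqs))

    mat = np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(n, L)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    if policy == "strict":
        if not valid.all():
            raise ValueError("non-ACGT character under strict comparison policy")
        valid = np.ones_like(valid)
    elif policy != "pairwise-deletion":
        raise ValueError(f"unknown comparison policy {policy!r}")

    total = 0
    for i in range(n - 1):
        diff = mat[i + 1 :] != mat[i]
        keep = valid[i + 1 :] & valid[i]
        total += int(np.count_nonzero(diff & keep))

    denom = n * (n + 1) if convention == "paper" else n * (n - 1)
    theta_pi = 2.0 * total / denom
    return AlignmentSummary(
        n=n, L=L, m=m, theta_pi=theta_pi,
        denominator_convention=convention, comparison_policy=policy,
    )


def read_fasta(path) -> list[Tuple[str, str]]:
    """Read an aligned FASTA file as a list of (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def summarize_fasta(
    path,
    convention: str = "paper",
    policy: str = "pairwise-deletion",
) -> AlignmentSummary:
    """Alignment summary straight from a FASTA file."""
    return summarize_alignment(read_fasta(path), convention=convention, policy=policy)
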