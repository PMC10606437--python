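"""Local protein alignment of eccDNA-encoded genes against known
herbicide-resistance candidate genes (GSTF1, GSTU2, OPR1, ...).

Alignments use BLOSUM62 with affine gaps (open 11, extend 1: a gap of
length L costs 11 + L). Bit scores and E-values follow the Karlin-Altschul
convention, bit = (lambda*S - ln K)/ln 2 and E = m*n*2^(-bit), with the
published gapped-BLOSUM62 constants lambda = 0.267, K = 0.041 as defaults
(the tool and parameters behind the reference table are unstated, so ours
are declared explicitly and exposed in config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

LAMBDA = 0.267
K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    pct_identity: float
    e_value: float
    bit_score: float
    aln_length: int
    raw_score: float
    query_sample: str | None = None
    exclusivity: str | None = None  # HR-only | HS-only | both


def _blosum62_x0() -> substitution_matrices.Array:
    """BLOSUM62 with X scored 0 against everything."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = _blosum62_x0()
    # first gap residue costs open+extend, each further residue costs extend
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    return a


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"empty protein sequence for {name}")
    bad = set(seq) - AA20 - {"X"}
    if bad:
        raise ValueError(f"{name}: non-amino-acid letters {sorted(bad)}")


def align_local(query: str, subject: str) -> tuple[float, float, int]:
    """Best local alignment of two proteins.

    Returns (raw score S, percent identity over alignment columns,
    alignment length in columns). A best score <= 0 means no local
    similarity; identity and length are reported as 0.
    """
    _check_protein(query, "query")
    _check_protein(subject, "subject")
    aligner = _protein_aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return float(score), 0.0, 0
    aln = aligner.align(query, subject)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    ident = 100.0 * counts.identities / columns if columns else 0.0
    return float(score), ident, int(columns)


def evalue(
    S: float, m: int, n: int, lam: float = LAMBDA, K_const: float = K
) -> tuple[float, float]:
    """Karlin-Altschul (bit score, E-value) for raw score S with query
    length m and database length n (total residues searched)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    bit = (lam * S - math.log(K_const)) / math.log(2.0)
    return bit, m * n * math.pow(2.0, -bit)


def screen(
    ecc_proteins: dict[str, str],
    candidates: dict[str, str],
    max_e: float = 1e-10,
    sample_of: dict[str, str] | None = None,
    group_map: dict[str, str] | None = None,
    lam: float = LAMBDA,
    K_const: float = K,
) -> list[AlignmentHit]:
    """Score every eccDNA protein against every candidate; keep the best hit
    per (query, subject) pair with E <= max_e, sorted by E ascending.

    ``sample_of`` maps query id -> sample; with ``group_map`` each hit is
    annotated with whether its subject was hit only from HR samples, only
    from HS samples, or both.
    """
    if not ecc_proteins or not candidates:
        raise ValueError("both protein sets must be non-empty")
    db_len = sum(len(s) for s in candidates.values())
    hits: list[AlignmentHit] = []
    for qid, qseq in sorted(ecc_proteins.items()):
        for sid, sseq in sorted(candidates.items()):
            S, ident, alen = align_local(qseq, sseq)
            if alen == 0:
                continue
            bit, E = evalue(S, len(qseq), db_len, lam, K_const)
            if E <= max_e:
                hits.append(
                    AlignmentHit(
                        query_id=qid, subject_id=sid,
                        pct_identity=round(ident, 3), e_value=E,
                        bit_score=round(bit, 1), aln_length=alen, raw_score=S,
                        query_sample=sample_of.get(qid) if sample_of else None,
                    )
                )
    if sample_of and group_map:
        by_subject: dict[str, set[str]] = {}
        for h in hits:
            by_subject.setdefault(h.subject_id, set()).add(group_map[sample_of[h.query_id]])
        for h in hits:
            groups = by_subject[h.subject_id]
            h.exclusivity = "both" if len(groups) > 1 else f"{next(iter(groups))}-only"
    hits.sort(key=lambda h: (h.e_value, h.query_id, h.subject_id))
    return hits
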