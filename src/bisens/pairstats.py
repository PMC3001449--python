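"""Per-alignment statistics.

For one pairwise structure alignment these functions compute the three
quantities the family-level regression consumes:

* **PNI** (percent sequence non-identity): ``100 * (1 - N_iden / N_algn)``,
  the fraction of aligned positions whose residues differ.
* **SNG** (standardized number of gaps): ``100 * N_gap / N_algn`` by
  default — the number of *indel events* (maximal internal unaligned
  regions, irrespective of their length) per 100 aligned residues.  The
  standard length is configurable.
* **RMSD**: root-mean-square deviation of the paired C-alpha atoms after
  optimal rigid-body superposition (proper rotations only — protein
  chirality forbids reflections).

Plus **PNS** (percent sequence non-similarity): the fraction of aligned
positions whose substitution-matrix score is zero or negative, a
similarity-aware analogue of PNI computed with BLOSUM50/62/80.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError
from .structio import DomainStructure, PairRecord, ResidueCorrespondence

SNG_STANDARD_LENGTH = 100.0  # residues; the "standard sequence length"

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignmentStats:
    """The regression observables of one pairwise alignment."""

    pni: float
    sng: float
    rmsd: float
    n_algn: int
    n_iden: int
    n_gap: int
    pns: float | None = None

    def __post_init__(self):
        if not 0 <= self.n_iden <= self.n_algn:
            raise ValidationError(f"n_iden={self.n_iden} outside [0, {self.n_algn}]")
        if self.rmsd < 0:
            raise ValidationError(f"negative rmsd {self.rmsd}")


def compute_pni(n_iden: int, n_algn: int) -> float:
    """Percent sequence non-identity, ``100 * (1 - N_iden/N_algn)``."""
    if n_algn <= 0:
        raise UndefinedStatisticError("PNI undefined for empty alignment (n_algn=0)")
    if not 0 <= n_iden <= n_algn:
        raise ValidationError(f"n_iden={n_iden} outside [0, n_algn={n_algn}]")
    return 100.0 * (1.0 - n_iden / n_algn)


def compute_sng(
    n_gap: int, n_algn: int, standard_length: float = SNG_STANDARD_LENGTH
) -> float:
    """Standardized number of gaps: indel events per ``standard_length`` aligned residues."""
    if n_algn <= 0:
        raise UndefinedStatisticError("SNG undefined for empty alignment (n_algn=0)")
    if n_gap < 0:
        raise ValidationError(f"negative n_gap {n_gap}")
    return standard_length * n_gap / n_algn


def count_gaps(
    corr: ResidueCorrespondence,
    len_a: int,
    len_b: int,
    count_terminal_gaps: bool = False,
) -> int:
    """Count indel events: maximal internal unaligned runs in either domain.

    A gap is one maximal run of unaligned residues lying strictly between
    two consecutive aligned pairs, counted per domain — a simultaneous skip
    in both domains between the same two aligned pairs contributes one run
    per domain.  Run length is irrelevant: a 1-residue and a 10-residue
    insertion are each one gap.  Terminal overhangs (unaligned residues
    before the first or after the last aligned pair) are alignment-extent
    artifacts and are excluded unless ``count_terminal_gaps`` is set.
    """
    corr.check_bounds(len_a, len_b)
    n = 0
    for (ia0, ib0), (ia1, ib1) in zip(corr.pairs, corr.pairs[1:]):
        if ia1 - ia0 > 1:
            n += 1
        if ib1 - ib0 > 1:
            n += 1
    if count_terminal_gaps and corr.pairs:
        first_a, first_b = corr.pairs[0]
        last_a, last_b = corr.pairs[-1]
        n += (first_a > 0) + (first_b > 0)
        n += (last_a < len_a - 1) + (last_b < len_b - 1)
    return n


def superpose_rmsd(coords_a, coords_b) -> float:
    """Optimal rigid-body RMSD between two equal-length C-alpha coordinate sets.

    Least-squares superposition over translations and proper rotations
    (Kabsch); reflections are excluded.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise InsufficientDataError(
            f"superposition needs >= 3 atom pairs, got {len(a)}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite coordinates")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    with warnings.catch_warnings():
        # collinear/planar point sets leave the rotation non-unique, but the
        # minimized RMSD is still well-defined
        warnings.filterwarnings(
            "ignore", message="Optimal rotation is not uniquely"
        )
        rot, _ = Rotation.align_vectors(ac, bc)
    # recompute from residuals: the reported rssd loses precision to
    # cancellation near zero
    diff = ac - rot.apply(bc)
    return float(np.sqrt((diff**2).sum() / len(a)))


def load_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix by name (BLOSUM50/62/80) or from a file path."""
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        return substitution_matrices.read(name)


def compute_pns(
    aligned_residue_pairs: Iterable[tuple[str, str]],
    matrix=None,
) -> float:
    """Percent sequence non-similarity under a substitution matrix.

    ``100 x (pairs scoring <= 0) / (scored pairs)``.  Pairs involving a
    non-standard residue code are skipped (with a warning giving the count);
    if nothing is scorable the statistic is undefined.
    """
    if matrix is None:
        matrix = load_matrix("BLOSUM62")
    n_scored = 0
    n_nonsim = 0
    n_skipped = 0
    for aa, bb in aligned_residue_pairs:
        if aa not in _STANDARD_AA or bb not in _STANDARD_AA:
            n_skipped += 1
            continue
        n_scored += 1
        if matrix[aa, bb] <= 0:
            n_nonsim += 1
    if n_skipped:
        warnings.warn(f"PNS: skipped {n_skipped} pair(s) with non-standard residues")
    if n_scored == 0:
        raise UndefinedStatisticError("PNS undefined: no scorable residue pairs")
    return 100.0 * n_nonsim / n_scored


def filter_accurate(
    records: Sequence[PairRecord], threshold: float = 3.0
) -> tuple[list[PairRecord], int]:
    """Keep accurate alignments: P-score strictly greater than ``threshold``.

    Records without a P-score cannot be gated and are dropped; returns
    ``(kept, n_dropped)``.
    """
    kept = [r for r in records if r.p_score is not None and r.p_score > threshold]
    return kept, len(records) - len(kept)


def stats_from_coordinates(
    sa: DomainStructure,
    sb: DomainStructure,
    corr: ResidueCorrespondence,
    matrix=None,
    sng_standard_length: float = SNG_STANDARD_LENGTH,
) -> AlignmentStats:
    """Compute PNI, SNG and superposition RMSD from coordinate-level inputs.

    ``n_algn`` is the number of aligned pairs, ``n_iden`` the pairs with
    equal 1-letter codes (non-standard codes count as non-identical unless
    literally equal), ``n_gap`` the internal unaligned-run count, and RMSD
    the optimal superposition of the paired C-alpha atoms.  PNS is attached
    when a substitution matrix is given.
    """
    corr.check_bounds(len(sa), len(sb))
    if len(corr) == 0:
        raise UndefinedStatisticError("empty correspondence")
    ia = np.fromiter((p[0] for p in corr.pairs), dtype=int)
    ib = np.fromiter((p[1] for p in corr.pairs), dtype=int)
    seq_a = sa.sequence
    seq_b = sb.sequence
    n_algn = len(corr)
    n_iden = sum(1 for i, j in corr.pairs if seq_a[i] == seq_b[j])
    n_gap = count_gaps(corr, len(sa), len(sb))
    rmsd = superpose_rmsd(sa.ca_coords[ia], sb.ca_coords[ib])
    pns = None
    if matrix is not None:
        pns = compute_pns(((seq_a[i], seq_b[j]) for i, j in corr.pairs), matrix)
    return AlignmentStats(
        pni=compute_pni(n_iden, n_algn),
        sng=compute_sng(n_gap, n_algn, standard_length=sng_standard_length),
        rmsd=rmsd,
        n_algn=n_algn,
        n_iden=n_iden,
        n_gap=n_gap,
        pns=pns,
    )
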