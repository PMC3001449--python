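"""Structure and alignment-table input/output.

This module defines the on-disk dialects consumed by the rest of the
pipeline:

* PDB-format structure files, from which a single-conformer C-alpha trace,
  the disulfide-bond count (SSBOND records), the experimental method
  (EXPDTA) and the crystallographic resolution (REMARK 2) are read.
* The pair-record TSV: one row per pairwise structure alignment, carrying
  the summary statistics (RMSD, N_algn, N_iden, N_gap, P-score, ...) that
  the per-family regression consumes.
* The residue-correspondence TSV: the ordered aligned residue pairs of one
  structure alignment, as 0-based positions into each domain's CA list.

Tabular dialects are UTF-8 TSV with a ``# bisens-format: v1`` first line and
``.`` for absent optional values.

Disulfide bonds are counted from SSBOND header records only: a bond counts
for a domain when *both* cysteine partners fall inside the domain's residue
range ("local" bonds).  A geometric fallback (SG-SG distance < 2.3 A) is
available behind an explicit flag for files without header records.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq1

from .errors import (
    EmptyStructureError,
    FormatError,
    PDBParseError,
    ValidationError,
)

FORMAT_TAG = "# bisens-format: v1"

#: mandatory pair-table columns, in canonical order
PAIR_COLUMNS = ["family_id", "domain_a", "domain_b", "rmsd", "n_algn", "n_iden", "n_gap"]
#: optional pair-table columns
PAIR_OPTIONAL = ["p_score", "z_score", "pns", "avg_disulfide"]

_SG_BOND_CUTOFF = 2.3  # Angstrom, S-S covalent bond upper bound


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DomainStructure:
    """C-alpha trace and metadata of one structural domain."""

    domain_id: str
    residues: list[tuple[int, str, str]]  # (residue_number, chain_id, 1-letter aa)
    ca_coords: np.ndarray  # (n, 3) float array, Angstrom
    n_disulfide: int = 0
    resolution_A: float | None = None
    method: str = "other"  # {"xray", "nmr", "other"}

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if len(self.residues) != len(self.ca_coords):
            raise ValidationError(
                f"{self.domain_id}: {len(self.residues)} residues but "
                f"{len(self.ca_coords)} CA coordinates"
            )
        if self.n_disulfide < 0:
            raise ValidationError(f"{self.domain_id}: negative disulfide count")
        seen: set[tuple[str, int]] = set()
        for num, chain, _ in self.residues:
            key = (chain, num)
            if key in seen:
                raise ValidationError(
                    f"{self.domain_id}: duplicate residue number {num} in chain {chain!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(aa for _, _, aa in self.residues)


@dataclass
class ResidueCorrespondence:
    """Ordered aligned residue pairs between two domains.

    Indices are 0-based positions into each domain's ordered CA list (not
    PDB residue numbers); both index sequences are strictly increasing, so
    the alignment has no crossings.
    """

    domain_a: str
    domain_b: str
    pairs: list[tuple[int, int]]

    def __post_init__(self):
        prev_a, prev_b = -1, -1
        for k, (ia, ib) in enumerate(self.pairs):
            if ia < 0 or ib < 0:
                raise ValidationError(f"pair {k}: negative index ({ia}, {ib})")
            if ia <= prev_a:
                raise ValidationError(
                    f"pair {k}: index_a {ia} not strictly increasing (previous {prev_a})"
                )
            if ib <= prev_b:
                raise ValidationError(
                    f"pair {k}: index_b {ib} not strictly increasing (previous {prev_b})"
                )
            prev_a, prev_b = ia, ib

    def __len__(self) -> int:
        return len(self.pairs)

    def swapped(self) -> "ResidueCorrespondence":
        """The same alignment viewed from domain B's side."""
        return ResidueCorrespondence(
            self.domain_b, self.domain_a, [(ib, ia) for ia, ib in self.pairs]
        )

    def check_bounds(self, len_a: int, len_b: int) -> None:
        if self.pairs:
            last_a, last_b = self.pairs[-1]
            if last_a >= len_a or last_b >= len_b:
                raise ValidationError(
                    f"correspondence indices ({last_a}, {last_b}) exceed domain "
                    f"lengths ({len_a}, {len_b})"
                )


@dataclass
class PairRecord:
    """Summary statistics of one pairwise structure alignment.

    The observation unit of the per-family regression.  ``p_score`` is the
    alignment significance reported by the structure matcher (negative log
    p-value; > 3 marks an accurate alignment) and is consumed as metadata,
    never computed here.
    """

    family_id: str
    domain_a: str
    domain_b: str
    rmsd: float
    n_algn: int
    n_iden: int
    n_gap: int
    p_score: float | None = None
    z_score: float | None = None
    pns: float | None = None
    avg_disulfide: float | None = None

    def __post_init__(self):
        if self.n_algn <= 0:
            raise ValidationError(f"{self.domain_a}/{self.domain_b}: n_algn must be positive")
        if not 0 <= self.n_iden <= self.n_algn:
            raise ValidationError(
                f"{self.domain_a}/{self.domain_b}: n_iden={self.n_iden} outside "
                f"[0, n_algn={self.n_algn}]"
            )
        if self.n_gap < 0:
            raise ValidationError(f"{self.domain_a}/{self.domain_b}: negative n_gap")
        if self.rmsd < 0 or not math.isfinite(self.rmsd):
            raise ValidationError(f"{self.domain_a}/{self.domain_b}: invalid rmsd {self.rmsd}")


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    """Parse the fields of one ATOM record (PDB fixed columns)."""
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record: {exc}", lineno) from None
    return name, altloc, resname, chain, resseq, icode, (x, y, z), occupancy


def _in_range(chain: str, resseq: int, domain_range) -> bool:
    if domain_range is None:
        return True
    rchain, start, end = domain_range
    return chain == rchain and start <= resseq <= end


def read_structure(
    pdb_source: TextIO | str,
    domain_range: tuple[str, int, int] | None = None,
    domain_id: str | None = None,
    infer_disulfides: bool = False,
) -> DomainStructure:
    """Read a C-alpha trace and disulfide count from PDB-format text.

    Parameters
    ----------
    pdb_source
        Open text stream or a string of PDB-format text with ATOM records.
    domain_range
        Optional ``(chain_id, start_residue, end_residue)`` restricting the
        domain; the whole file is used when absent.
    domain_id
        Identifier stored on the returned structure.
    infer_disulfides
        When true and the file has no SSBOND records, infer bonds from
        SG-SG distances below 2.3 A between cysteine residues in range.

    Notes
    -----
    Only altloc ' ' or 'A' CA atoms are kept; duplicate CA atoms for one
    residue keep the highest-occupancy conformer.  Only the first MODEL of a
    multi-model file is read.  SSBOND bonds count only when both cysteines
    lie inside ``domain_range`` — the "local domain" rule.
    """
    if isinstance(pdb_source, str):
        pdb_source = io.StringIO(pdb_source)

    residues: list[tuple[int, str, str]] = []
    coords: list[tuple[float, float, float]] = []
    occupancies: list[float] = []
    index_of: dict[tuple[str, int, str], int] = {}
    ssbonds: list[tuple[str, int, str, int]] = []
    sg_atoms: list[tuple[str, int, np.ndarray]] = []
    method = "other"
    resolution: float | None = None
    in_first_model = True

    for lineno, raw in enumerate(pdb_source, start=1):
        record = raw[:6]
        if record == "ENDMDL":
            in_first_model = False
        if not in_first_model:
            continue
        if record in ("ATOM  ", "HETATM"):
            name, altloc, resname, chain, resseq, icode, xyz, occ = _parse_atom_line(
                raw, lineno
            )
            if record == "HETATM" and resname != "MSE":
                continue
            if altloc not in (" ", "A"):
                continue
            if not _in_range(chain, resseq, domain_range):
                continue
            if name == "CA":
                key = (chain, resseq, icode)
                if key in index_of:
                    i = index_of[key]
                    if occ > occupancies[i]:  # keep highest-occupancy conformer
                        coords[i] = xyz
                        occupancies[i] = occ
                else:
                    index_of[key] = len(residues)
                    residues.append((resseq, chain, seq1(resname)))
                    coords.append(xyz)
                    occupancies.append(occ)
            elif name == "SG" and resname == "CYS":
                sg_atoms.append((chain, resseq, np.asarray(xyz)))
        elif record == "SSBOND":
            try:
                chain1 = raw[15]
                seq1_ = int(raw[17:21])
                chain2 = raw[29]
                seq2_ = int(raw[31:35])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed SSBOND record: {exc}", lineno) from None
            ssbonds.append((chain1, seq1_, chain2, seq2_))
        elif record == "EXPDTA":
            text = raw[10:].upper()
            if "NMR" in text:
                method = "nmr"
            elif "X-RAY" in text:
                method = "xray"
        elif record == "REMARK" and raw[7:10].strip() == "2":
            tokens = raw.upper().split()
            if "RESOLUTION." in tokens:
                i = tokens.index("RESOLUTION.")
                if i + 1 < len(tokens):
                    try:
                        resolution = float(tokens[i + 1])
                    except ValueError:
                        pass  # "NOT APPLICABLE" etc.

    if not residues:
        raise EmptyStructureError(
            f"no CA atoms found{' in range ' + repr(domain_range) if domain_range else ''}"
        )

    n_ss = sum(
        1
        for c1, s1, c2, s2 in ssbonds
        if _in_range(c1, s1, domain_range) and _in_range(c2, s2, domain_range)
    )
    if not ssbonds and infer_disulfides and len(sg_atoms) >= 2:
        for i in range(len(sg_atoms)):
            for j in range(i + 1, len(sg_atoms)):
                if np.linalg.norm(sg_atoms[i][2] - sg_atoms[j][2]) < _SG_BOND_CUTOFF:
                    n_ss += 1

    return DomainStructure(
        domain_id=domain_id or "unknown",
        residues=residues,
        ca_coords=np.asarray(coords, dtype=float),
        n_disulfide=n_ss,
        resolution_A=resolution,
        method=method,
    )


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

def _read_tagged_tsv(source: TextIO | str) -> pd.DataFrame:
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#", na_values=["."], dtype={0: str})
    return df


def read_pair_table(tsv_source: TextIO | str) -> list[PairRecord]:
    """Read a pair-record TSV into validated :class:`PairRecord` objects.

    Rows violating record invariants raise :class:`ValidationError` naming
    the offending 0-based data-row index.
    """
    df = _read_tagged_tsv(tsv_source)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pair table missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        try:
            records.append(
                PairRecord(
                    family_id=str(row["family_id"]),
                    domain_a=str(row["domain_a"]),
                    domain_b=str(row["domain_b"]),
                    rmsd=float(row["rmsd"]),
                    n_algn=int(row["n_algn"]),
                    n_iden=int(row["n_iden"]),
                    n_gap=int(row["n_gap"]),
                    p_score=opt("p_score"),
                    z_score=opt("z_score"),
                    pns=opt("pns"),
                    avg_disulfide=opt("avg_disulfide"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"pair table row {i}: {exc}") from None
    return records


def write_pair_table(records: Iterable[PairRecord], dest: TextIO) -> None:
    """Write pair records in the canonical tagged-TSV dialect."""
    dest.write(FORMAT_TAG + "\n")
    cols = PAIR_COLUMNS + PAIR_OPTIONAL
    dest.write("\t".join(cols) + "\n")
    for r in records:
        row = [
            r.family_id,
            r.domain_a,
            r.domain_b,
            format(r.rmsd, ".6g"),
            str(r.n_algn),
            str(r.n_iden),
            str(r.n_gap),
        ]
        for v in (r.p_score, r.z_score, r.pns, r.avg_disulfide):
            row.append("." if v is None else format(v, ".6g"))
        dest.write("\t".join(row) + "\n")


def pair_records_to_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    """Tabular view of pair records (columns in canonical order)."""
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in records],
            "domain_a": [r.domain_a for r in records],
            "domain_b": [r.domain_b for r in records],
            "rmsd": [r.rmsd for r in records],
            "n_algn": [r.n_algn for r in records],
            "n_iden": [r.n_iden for r in records],
            "n_gap": [r.n_gap for r in records],
            "p_score": [r.p_score for r in records],
            "z_score": [r.z_score for r in records],
            "pns": [r.pns for r in records],
            "avg_disulfide": [r.avg_disulfide for r in records],
        }
    )


# ---------------------------------------------------------------------------
# correspondence table
# ---------------------------------------------------------------------------

def read_correspondence(source: TextIO | str) -> ResidueCorrespondence:
    """Read an aligned-residue correspondence from its two-column TSV.

    Format: optional ``# bisens-format`` tag, then ``# domain_a: <id>`` and
    ``# domain_b: <id>`` comments, a ``index_a\\tindex_b`` header, and one
    0-based index pair per row, strictly increasing in both columns.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    domain_a = domain_b = "unknown"
    pairs: list[tuple[int, int]] = []
    header_seen = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("domain_a:"):
                domain_a = body.split(":", 1)[1].strip()
            elif body.startswith("domain_b:"):
                domain_b = body.split(":", 1)[1].strip()
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols[:2] != ["index_a", "index_b"]:
                raise FormatError(
                    f"line {lineno}: expected header 'index_a\\tindex_b', got {line!r}"
                )
            header_seen = True
            continue
        fields = line.split("\t")
        try:
            pairs.append((int(fields[0]), int(fields[1])))
        except (ValueError, IndexError):
            raise FormatError(f"line {lineno}: malformed index pair {line!r}") from None
    if not header_seen:
        raise FormatError("correspondence file has no header row")
    return ResidueCorrespondence(domain_a, domain_b, pairs)


def write_correspondence(corr: ResidueCorrespondence, dest: TextIO) -> None:
    dest.write(FORMAT_TAG + "\n")
    dest.write(f"# domain_a: {corr.domain_a}\n")
    dest.write(f"# domain_b: {corr.domain_b}\n")
    dest.write("index_a\tindex_b\n")
    for ia, ib in corr.pairs:
        dest.write(f"{ia}\t{ib}\n")


# ---------------------------------------------------------------------------
# PDB writing (toy structures from the simulator)
# ---------------------------------------------------------------------------

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_structure(structure: DomainStructure, dest: TextIO) -> None:
    """Write a CA-only trace as minimal PDB-format text."""
    for i, ((resnum, chain, aa), xyz) in enumerate(
        zip(structure.residues, structure.ca_coords), start=1
    ):
        resname = _AA3.get(aa, "UNK")
        x, y, z = xyz
        dest.write(
            f"ATOM  {i:5d}  CA  {resname} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
        )
    dest.write("END\n")
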