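"""SNP genotype data model and I/O.

Genotypes of fully homozygous lines (inbreds and doubled haploids) are coded
per locus as +1 (homozygous for the major allele), -1 (homozygous minor) and
0 (missing), following the coding convention common in maize breeding
analyses.  Raw biallelic calls read from HapMap or VCF files pass through
:func:`encode_genotypes` to obtain the coded matrix.

Coordinates are 1-based base-pair positions as in HapMap/VCF; centimorgan
positions are carried only for simulated data (the meiosis model needs them).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing coded call.
MISSING: int = 0

# IUPAC single-letter codes for diploid calls used in HapMap files.
_IUPAC = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "", "-": "",
}

_MISSING_RAW = {"", "NN", "N", "--", "..", "./.", ".|.", "."}


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP marker.

    position_bp is 1-based; position_cM is optional and only populated for
    simulated maps (used by the meiosis simulator).
    """

    id: str
    chromosome: str
    position_bp: int
    position_cM: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"marker {self.id}: position_bp must be >= 1")


@dataclass
class RawGenotypes:
    """Biallelic calls as two-letter allele strings, pending encoding.

    ``calls[i, j]`` is e.g. ``"AA"``, ``"AT"`` or ``""`` (missing) for line i
    at marker j.
    """

    line_ids: list[str]
    markers: list[Marker]
    calls: np.ndarray  # dtype=object / str, shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        _check_ids(self.line_ids, self.markers, self.calls.shape)


@dataclass
class GenotypeMatrix:
    """Lines x markers matrix of coded calls in {-1, +1, 0=missing}."""

    line_ids: list[str]
    markers: list[Marker]
    calls: np.ndarray  # dtype=int8, shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        _check_ids(self.line_ids, self.markers, self.calls.shape)
        bad = ~np.isin(self.calls, (-1, 1, MISSING))
        if bad.any():
            raise ValueError("coded calls must be in {-1, +1, 0}")
        self._index = {lid: i for i, lid in enumerate(self.line_ids)}

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def row(self, line_id: str) -> np.ndarray:
        """Coded calls for one line."""
        try:
            return self.calls[self._index[line_id]]
        except KeyError:
            raise KeyError(f"unknown line id: {line_id}") from None

    def subset_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        idx = [self._index[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.markers, self.calls[idx].copy())


@dataclass
class Pedigree:
    """DH-inducer to parent-pair assignments.

    The family id is determined by the unordered parent pair; PGC and the
    top/bottom phenotype groups are always computed within family.
    ``reference_lines`` designates the parents anchoring the nested (NAM-style)
    population partition.
    """

    records: list[tuple[str, str, str, str]]  # (dhi_id, parent1, parent2, family_id)
    reference_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for dhi, p1, p2, _fam in self.records:
            if p1 == p2:
                raise ValueError(f"{dhi}: parent1 and parent2 are identical ({p1})")
            if dhi in seen:
                raise ValueError(f"duplicate DHI id in pedigree: {dhi}")
            seen.add(dhi)

    @classmethod
    def from_parent_pairs(
        cls,
        pairs: dict[str, tuple[str, str]],
        reference_lines: list[str] | None = None,
    ) -> "Pedigree":
        """Build from {dhi_id: (parent1, parent2)}; family id is 'A/B' with the
        unordered pair sorted."""
        records = [
            (dhi, p1, p2, family_id(p1, p2)) for dhi, (p1, p2) in pairs.items()
        ]
        return cls(records, list(reference_lines or []))

    @property
    def dhi_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def families(self) -> dict[str, list[str]]:
        """family_id -> list of DHI ids."""
        fams: dict[str, list[str]] = {}
        for dhi, _p1, _p2, fam in self.records:
            fams.setdefault(fam, []).append(dhi)
        return fams

    @property
    def family_parents(self) -> dict[str, tuple[str, str]]:
        """family_id -> (parent1, parent2) as listed in the records."""
        out: dict[str, tuple[str, str]] = {}
        for _dhi, p1, p2, fam in self.records:
            out.setdefault(fam, (p1, p2))
        return out

    def parents_of(self, dhi_id: str) -> tuple[str, str]:
        for dhi, p1, p2, _fam in self.records:
            if dhi == dhi_id:
                return (p1, p2)
        raise KeyError(f"unknown DHI id: {dhi_id}")


def family_id(parent1: str, parent2: str) -> str:
    """Canonical family label for an unordered parent pair."""
    return "/".join(sorted((parent1, parent2)))


def _check_ids(line_ids, markers, shape) -> None:
    if len(set(line_ids)) != len(line_ids):
        raise ValueError("line_ids must be unique")
    mids = [m.id for m in markers]
    if len(set(mids)) != len(mids):
        raise ValueError("marker ids must be unique")
    if shape != (len(line_ids), len(markers)):
        raise ValueError(
            f"calls shape {shape} inconsistent with "
            f"{len(line_ids)} lines x {len(markers)} markers"
        )


def _chrom_sort_key(chrom: str):
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom, flags=re.IGNORECASE)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def _sort_and_dedup(markers: list[Marker], calls: np.ndarray):
    order = sorted(
        range(len(markers)),
        key=lambda j: (_chrom_sort_key(markers[j].chromosome), markers[j].position_bp),
    )
    markers = [markers[j] for j in order]
    calls = calls[:, order]
    prev = None
    for mk in markers:
        key = (mk.chromosome, mk.position_bp)
        if key == prev:
            warnings.warn(f"duplicate marker position {key}; positions should be unique")
        prev = key
    return markers, calls


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_HAPMAP_META_COLS = 11


def read_hapmap(path) -> RawGenotypes:
    """Read a HapMap tab-separated genotype file.

    The standard layout has 11 metadata columns (rs#, alleles, chrom, pos,
    strand, assembly#, center, protLSID, assayLSID, panelLSID, QCcode)
    followed by one column per line.  Calls may be single-letter IUPAC codes
    or two-letter diploid calls; N (or NN) is missing.  Loci with more than
    two alleles among the observed calls are excluded with a warning.

    Markers are returned sorted by (chromosome, position).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_META_COLS or not header[0].lower().startswith("rs"):
            raise FormatError(
                f"{path}: not a HapMap header (needs >= {_HAPMAP_META_COLS + 1} "
                "tab-separated columns starting with 'rs#')"
            )
        line_ids = header[_HAPMAP_META_COLS:]
        markers: list[Marker] = []
        columns: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            raw_calls = [_decode_call(c) for c in fields[_HAPMAP_META_COLS:]]
            alleles = {a for call in raw_calls for a in call}
            if len(alleles) > 2:
                logger.warning(
                    "excluding marker %s: %d alleles observed", fields[0], len(alleles)
                )
                continue
            try:
                pos = int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            markers.append(Marker(fields[0], fields[2], pos))
            columns.append(raw_calls)
    calls = np.array(columns, dtype=object).T if columns else np.empty((len(line_ids), 0), object)
    markers, calls = _sort_and_dedup(markers, calls)
    return RawGenotypes(line_ids, markers, calls)


def _decode_call(token: str) -> str:
    token = token.strip().upper()
    if token in _MISSING_RAW:
        return ""
    if len(token) == 1:
        if token not in _IUPAC:
            raise FormatError(f"unknown single-letter call {token!r}")
        return _IUPAC[token]
    if len(token) == 2 and all(a in "ACGT" for a in token):
        return token
    raise FormatError(f"unparseable genotype call {token!r}")


def read_vcf(path) -> RawGenotypes:
    """Read biallelic records from a VCF (v4.x) into raw calls.

    Requires a GT field; ``./.`` becomes missing; multiallelic records are
    excluded with a warning.  Markers are sorted by (chromosome, position).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    if not line_ids:
        raise FormatError(f"{path}: VCF has no sample columns")
    markers: list[Marker] = []
    columns: list[list[str]] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.ALT[0] in (".", ""):
            logger.warning("excluding multiallelic/invalid record %s:%s", rec.CHROM, rec.POS)
            continue
        alleles = (rec.REF, rec.ALT[0])
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        if gts is None:
            raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} has no GT field")
        col = []
        for g in gts:
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                col.append("")
            else:
                col.append(alleles[a0] + alleles[a1])
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        markers.append(Marker(mid, rec.CHROM, rec.POS))
        columns.append(col)
    calls = np.array(columns, dtype=object).T if columns else np.empty((len(line_ids), 0), object)
    markers, calls = _sort_and_dedup(markers, calls)
    return RawGenotypes(line_ids, markers, calls)


def write_hapmap(g: GenotypeMatrix, path, major: str = "A", minor: str = "T") -> None:
    """Write a coded matrix as a HapMap file (+1 -> major allele, -1 -> minor)."""
    meta = ["NA"] * (_HAPMAP_META_COLS - 4)
    with open(path, "w") as fh:
        header = [
            "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
            "protLSID", "assayLSID", "panelLSID", "QCcode",
        ] + list(g.line_ids)
        fh.write("\t".join(header) + "\n")
        code = {1: major * 2, -1: minor * 2, MISSING: "NN"}
        for j, mk in enumerate(g.markers):
            row = [mk.id, f"{major}/{minor}", mk.chromosome, str(mk.position_bp)] + meta
            row += [code[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def write_vcf(g: GenotypeMatrix, path, major: str = "A", minor: str = "T") -> None:
    """Write a coded matrix as an uncompressed VCF v4.2 (REF=major, ALT=minor)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for mk in g.markers:
            if mk.chromosome not in chroms:
                chroms.append(mk.chromosome)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.line_ids) + "\n"
        )
        gt = {1: "0/0", -1: "1/1", MISSING: "./."}
        for j, mk in enumerate(g.markers):
            row = [mk.chromosome, str(mk.position_bp), mk.id, major, minor, ".", ".", ".", "GT"]
            row += [gt[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def read_pedigree(path, reference_lines: list[str] | None = None) -> Pedigree:
    """Read a pedigree CSV with header ``dhi_id,parent1,parent2``."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    required = {"dhi_id", "parent1", "parent2"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: pedigree needs columns {sorted(required)}")
    pairs = {r.dhi_id: (r.parent1, r.parent2) for r in df.itertuples()}
    return Pedigree.from_parent_pairs(pairs, reference_lines)


# ---------------------------------------------------------------------------
# Encoding and filtering
# ---------------------------------------------------------------------------

def encode_genotypes(raw: RawGenotypes, het_policy: str = "error") -> GenotypeMatrix:
    """Code biallelic calls as +1 (homozygous major) / -1 (homozygous minor).

    The major allele at each locus is the one with frequency >= 0.5 among
    non-missing calls; an exact 0.5/0.5 tie is broken in favour of the
    alphabetically first allele so that the coding is reproducible.

    DH lines are fully homozygous, so a heterozygous call is evidence of a
    data problem: ``het_policy="error"`` (default) raises naming the line and
    marker, ``"set_missing"`` records the cell as missing.
    """
    if het_policy not in ("error", "set_missing"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    n, m = raw.calls.shape
    coded = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        counts: dict[str, int] = {}
        for call in raw.calls[:, j]:
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"marker {raw.markers[j].id}: more than two alleles")
        # Tie at 0.5 broken alphabetically; monomorphic locus has one allele.
        major = max(sorted(counts), key=lambda a: counts[a]) if counts else None
        for i in range(n):
            call = raw.calls[i, j]
            if call == "":
                continue
            if call[0] != call[1]:
                if het_policy == "error":
                    raise ValueError(
                        f"heterozygous call {call!r} for line {raw.line_ids[i]} "
                        f"at marker {raw.markers[j].id} (DH lines must be homozygous)"
                    )
                continue  # set_missing
            coded[i, j] = 1 if call[0] == major else -1
    return GenotypeMatrix(list(raw.line_ids), list(raw.markers), coded)


def minor_allele_freq(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency over non-missing lines (NaN if all missing)."""
    plus = (g.calls == 1).sum(axis=0).astype(float)
    nonmiss = (g.calls != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = plus / nonmiss
    return np.minimum(p, 1.0 - p)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop markers with minor allele frequency strictly below ``threshold``.

    The boundary is retained (MAF == threshold passes), reading the usual
    "less than 5%" filtering rule literally.  Markers where every call is
    missing are dropped.  Idempotent; marker order preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    maf = minor_allele_freq(g)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold - 1e-12)[0]
    logger.info("MAF filter: %d of %d markers retained", len(keep), g.n_markers)
    return GenotypeMatrix(
        list(g.line_ids), [g.markers[j] for j in keep], g.calls[:, keep].copy()
    )


def polymorphic_loci(p1_row: np.ndarray, p2_row: np.ndarray) -> np.ndarray:
    """Indices where both parents are non-missing and carry different alleles."""
    p1 = np.asarray(p1_row)
    p2 = np.asarray(p2_row)
    if p1.shape != p2.shape:
        raise ValueError(f"length mismatch: {p1.shape} vs {p2.shape}")
    mask = (p1 != MISSING) & (p2 != MISSING) & (p1 != p2)
    return np.where(mask)[0]
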