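"""Contact-file parsing, genome binning, binarization and structure I/O.

The modelling pipeline consumes single-cell Hi-C contacts as genomic
position pairs, maps them onto fixed-size bins ("beads"), and collapses
any multiplicity to a binary 0/1 bead-pair matrix — the extremely sparse
input regime the reconstruction is designed for.  Bins are half-open
``[k*res, (k+1)*res)`` and bead indices are 0-based and globally
contiguous across chromosomes (and haplotype copies).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContactRecord",
    "GenomeBinning",
    "BinaryContactMatrix",
    "Structure",
    "read_chrom_sizes",
    "read_contact_pairs",
    "bin_contacts",
    "downsample_contacts",
    "write_structure",
    "read_structure",
]

_HAP_PAREN = re.compile(r"^(?P<chrom>.+)\((?P<hap>[^()]+)\)$")
_HAP_SUFFIX = re.compile(r"^(?P<chrom>.+)_(?P<hap>mat|pat)$")


def _split_haplotype(label: str) -> tuple[str, Optional[str]]:
    """Normalize ``chr1(mat)`` / ``chr1_mat`` style labels into (chrom, hap)."""
    m = _HAP_PAREN.match(label)
    if m:
        return m.group("chrom"), m.group("hap")
    m = _HAP_SUFFIX.match(label)
    if m:
        return m.group("chrom"), m.group("hap")
    return label, None


@dataclass(frozen=True)
class ContactRecord:
    """One raw genomic contact pair (before binning)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    hap_a: Optional[str] = None
    hap_b: Optional[str] = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.chrom_a or not self.chrom_b:
            raise ValueError("chromosome labels must be nonempty")
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError("positions must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")


ContactList = list  # list[ContactRecord]


class GenomeBinning:
    """Chromosome (and haplotype) sizes plus a global bead indexing.

    Parameters
    ----------
    chrom_order
        Ordered ``(chromosome, haplotype-or-None, length_bp)`` triples. Each
        (chromosome, haplotype) pair becomes an independent bead chain.
    resolution
        Bin size in bp. A chromosome of length L contributes ceil(L/res)
        beads.
    """

    def __init__(
        self,
        chrom_order: Sequence[tuple[str, Optional[str], int]],
        resolution: int,
    ) -> None:
        if resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.chrom_order: tuple[tuple[str, Optional[str], int], ...] = tuple(
            (str(c), h, int(L)) for c, h, L in chrom_order
        )
        seen = set()
        for c, h, L in self.chrom_order:
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
            if (c, h) in seen:
                raise ValueError(f"duplicate chromosome {(c, h)}")
            seen.add((c, h))
        self.resolution = int(resolution)
        self.n_bins = tuple(
            -(-L // self.resolution) for _, _, L in self.chrom_order
        )
        offs = np.concatenate([[0], np.cumsum(self.n_bins)])
        self.bead_offsets: dict[tuple[str, Optional[str]], int] = {
            (c, h): int(offs[k]) for k, (c, h, _) in enumerate(self.chrom_order)
        }
        self._offsets = offs
        self.n_beads = int(offs[-1])

    # -- indexing -------------------------------------------------------

    def bead_index(self, chrom: str, hap: Optional[str], pos: int) -> Optional[int]:
        """Global bead index for a genomic position, or None if the
        (chromosome, haplotype) is absent or the position exceeds the
        chromosome length."""
        key = (chrom, hap)
        off = self.bead_offsets.get(key)
        if off is None:
            return None
        k = next(i for i, (c, h, _) in enumerate(self.chrom_order) if (c, h) == key)
        if pos >= self.chrom_order[k][2]:
            return None
        return off + pos // self.resolution

    def chrom_id_array(self) -> np.ndarray:
        """int32 chain identifier per bead (one id per chromosome copy)."""
        out = np.empty(self.n_beads, dtype=np.int32)
        for k in range(len(self.chrom_order)):
            out[self._offsets[k]: self._offsets[k + 1]] = k
        return out

    def bead_table(self) -> list[tuple[str, Optional[str], int, int]]:
        """Per-bead (chrom, hap, bin_start, bin_end) rows."""
        rows = []
        for k, (c, h, L) in enumerate(self.chrom_order):
            for b in range(self.n_bins[k]):
                start = b * self.resolution
                rows.append((c, h, start, min(start + self.resolution, L)))
        return rows

    def genomic_position(self) -> np.ndarray:
        """Per-bead bin midpoint (bp) within its own chromosome."""
        out = np.empty(self.n_beads, dtype=np.float64)
        i = 0
        for k, (_, _, L) in enumerate(self.chrom_order):
            for b in range(self.n_bins[k]):
                start = b * self.resolution
                out[i] = (start + min(start + self.resolution, L)) / 2.0
                i += 1
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeBinning)
            and self.chrom_order == other.chrom_order
            and self.resolution == other.resolution
        )

    def __repr__(self) -> str:
        return (
            f"GenomeBinning({len(self.chrom_order)} chains, "
            f"res={self.resolution}, l={self.n_beads})"
        )

    @classmethod
    def from_chrom_sizes(
        cls,
        path: str | Path,
        resolution: int,
        haplotypes: Optional[Sequence[str]] = None,
    ) -> "GenomeBinning":
        """Build from a UCSC-style two-column chrom.sizes file.

        ``haplotypes`` duplicates every chromosome into the given copies
        (e.g. ``("mat", "pat")`` for a diploid genome).
        """
        sizes = read_chrom_sizes(path)
        order: list[tuple[str, Optional[str], int]] = []
        for name, length in sizes:
            if haplotypes:
                for h in haplotypes:
                    order.append((name, h, length))
            else:
                order.append((name, None, length))
        return cls(order, resolution)


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Parse a UCSC chrom.sizes file (name<TAB>length)."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {ln}: expected 'name length'")
            try:
                out.append((parts[0], int(parts[1])))
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: bad length {parts[1]!r}") from e
    return out


@dataclass
class BinaryContactMatrix:
    """Symmetric sparse 0/1 bead-pair matrix — the reconstruction input.

    ``pairs`` holds unique unordered bead pairs as an (m, 2) int array with
    i < j on every row; every listed pair has value 1, everything else 0.
    """

    n_beads: int
    pairs: np.ndarray
    binning: GenomeBinning

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if p.size and (p.min() < 0 or p.max() >= self.n_beads):
            raise ValueError("bead index out of range")
        if p.size and np.any(p[:, 0] >= p[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        self.pairs = p

    @property
    def n_contacts(self) -> int:
        return int(self.pairs.shape[0])

    def to_csr(self):
        """Symmetric scipy CSR view (no self-loops)."""
        from scipy.sparse import csr_matrix

        i, j = self.pairs[:, 0], self.pairs[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(rows.shape[0], dtype=np.float64)
        return csr_matrix((data, (rows, cols)), shape=(self.n_beads, self.n_beads))

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_beads, dtype=np.float64)
        np.add.at(d, self.pairs[:, 0], 1.0)
        np.add.at(d, self.pairs[:, 1], 1.0)
        return d

    def intra_inter_counts(self) -> tuple[int, int]:
        """(intra-chain, inter-chain) contact counts on the binary matrix."""
        cid = self.binning.chrom_id_array()
        if self.n_contacts == 0:
            return 0, 0
        same = cid[self.pairs[:, 0]] == cid[self.pairs[:, 1]]
        return int(same.sum()), int((~same).sum())


@dataclass
class Structure:
    """Per-bead 3D coordinates (lattice units) inside a cubic box."""

    coords: np.ndarray
    binning: GenomeBinning
    box_side: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if c.shape[0] != self.binning.n_beads:
            raise ValueError(
                f"coords rows ({c.shape[0]}) != bead count ({self.binning.n_beads})"
            )
        self.coords = c

    @property
    def n_beads(self) -> int:
        return int(self.coords.shape[0])

    def copy(self) -> "Structure":
        return Structure(self.coords.copy(), self.binning, self.box_side)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def read_contact_pairs(path: str | Path, format: str = "pairs") -> ContactList:
    """Parse a contact file into ContactRecords.

    ``format="pairs"``: whitespace-delimited ``chrA posA chrB posB [count]``,
    ``#`` comments allowed.  ``format="ncc"``: the nuc_processing NCC dialect;
    only the two chromosome/coordinate field groups (whitespace fields 0/1 and
    6/7) are consumed, everything else on the line is ignored.
    """
    if format not in ("pairs", "ncc"):
        raise ValueError(f"unknown format {format!r}")
    records: ContactList = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if format == "pairs":
                    if len(parts) < 4:
                        raise ValueError("expected >= 4 columns")
                    ca, ha = _split_haplotype(parts[0])
                    cb, hb = _split_haplotype(parts[2])
                    count = int(parts[4]) if len(parts) >= 5 else 1
                    rec = ContactRecord(
                        ca, int(parts[1]), cb, int(parts[3]),
                        hap_a=ha, hap_b=hb, count=count,
                    )
                else:  # ncc
                    if len(parts) < 8:
                        raise ValueError("expected >= 8 columns in NCC record")
                    ca, ha = _split_haplotype(parts[0])
                    cb, hb = _split_haplotype(parts[6])
                    rec = ContactRecord(
                        ca, int(parts[1]), cb, int(parts[7]),
                        hap_a=ha, hap_b=hb,
                    )
            except ValueError as e:
                raise ValueError(f"{path}: malformed line {ln}: {e}") from e
            records.append(rec)
    return records


def bin_contacts(contacts: Iterable[ContactRecord], binning: GenomeBinning) -> BinaryContactMatrix:
    """Bin contacts to beads and binarize.

    Any multiplicity collapses to 1; same-bead (self) pairs are dropped;
    contacts on chromosomes absent from the binning are dropped with a
    logged count.
    """
    pairs = set()
    dropped = 0
    for rec in contacts:
        ia = binning.bead_index(rec.chrom_a, rec.hap_a, rec.pos_a)
        ib = binning.bead_index(rec.chrom_b, rec.hap_b, rec.pos_b)
        if ia is None or ib is None:
            dropped += 1
            continue
        if ia == ib:
            continue
        pairs.add((ia, ib) if ia < ib else (ib, ia))
    if dropped:
        logger.info("bin_contacts: dropped %d contacts outside the binning", dropped)
    arr = (
        np.array(sorted(pairs), dtype=np.int64)
        if pairs
        else np.empty((0, 2), dtype=np.int64)
    )
    return BinaryContactMatrix(binning.n_beads, arr, binning)


def downsample_contacts(contacts: ContactList, fraction: float, seed: int) -> ContactList:
    """Uniform without-replacement subsample of exactly floor(fraction*n)
    records (deterministic per seed; input order preserved)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = len(contacts)
    k = int(np.floor(fraction * n))
    if k == n:
        return list(contacts)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [contacts[i] for i in idx]


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

_STRUCT_COLUMNS = ["chrom", "hap", "bin_start", "bin_end", "x", "y", "z"]


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as TSV: header plus one row per bead
    (chrom, haplotype or '.', bin_start, bin_end, x, y, z to 6 decimals)."""
    rows = structure.binning.bead_table()
    with open(path, "w") as fh:
        fh.write(f"#resolution={structure.binning.resolution}\n")
        fh.write(f"#box_side={structure.box_side:.6f}\n")
        fh.write("\t".join(_STRUCT_COLUMNS) + "\n")
        for (c, h, s, e), xyz in zip(rows, structure.coords):
            fh.write(
                f"{c}\t{h if h is not None else '.'}\t{s}\t{e}\t"
                f"{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}\n"
            )


def read_structure(path: str | Path) -> Structure:
    """Read a structure TSV written by :func:`write_structure`."""
    resolution = None
    box_side = None
    coords = []
    chrom_rows: list[tuple[str, Optional[str], int]] = []  # (chrom, hap, bin_end)
    header_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#resolution="):
                resolution = int(line.split("=", 1)[1])
                continue
            if line.startswith("#box_side="):
                box_side = float(line.split("=", 1)[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts != _STRUCT_COLUMNS:
                    raise ValueError(f"{path}: line {ln}: unexpected header {parts}")
                header_seen = True
                continue
            if len(parts) != 7:
                raise ValueError(f"{path}: line {ln}: expected 7 columns, got {len(parts)}")
            c = parts[0]
            h = None if parts[1] == "." else parts[1]
            chrom_rows.append((c, h, int(parts[3])))
            coords.append([float(parts[4]), float(parts[5]), float(parts[6])])
    if resolution is None or box_side is None or not header_seen:
        raise ValueError(f"{path}: missing header metadata")
    # reconstruct chromosome order and lengths from the bead rows
    order: list[tuple[str, Optional[str], int]] = []
    for c, h, end in chrom_rows:
        if order and order[-1][0] == c and order[-1][1] == h:
            order[-1] = (c, h, end)
        else:
            order.append((c, h, end))
    binning = GenomeBinning(order, resolution)
    arr = (
        np.array(coords, dtype=np.float64)
        if coords
        else np.empty((0, 3), dtype=np.float64)
    )
    if arr.shape[0] != binning.n_beads:
        raise ValueError(f"{path}: bead rows inconsistent with reconstructed binning")
    return Structure(arr, binning, box_side)
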