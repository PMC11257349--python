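"""Shared in-memory data model and file I/O.

The pipeline's central containers live here: :class:`SampleSheet` (sample ->
sex/species/population labels that drive all sex-stratified statistics),
:class:`GenotypeTable` (biallelic SNP genotypes, per-sample depth and optional
phased haplotypes) and :class:`WindowSet` (genomic windows).

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  VCF positions are 1-based;
the conversion between the two lives in :func:`to_one_based` /
:func:`to_zero_based` and is applied only at the VCF boundary.

Genotype encoding
-----------------
Genotypes are stored as small integers: ``HOM_REF=0``, ``HET=1``,
``HOM_ALT=2``, ``HALF_CALL=3`` (exactly one allele called, e.g. ``0/.``) and
``MISSING=-1``.  Half-calls are kept distinct from missing because the
candidate-site criterion "not more than one female homozygous, allowing one
female with one allele not called" must see them.  When no haplotype matrix is
present the identity of the single called allele is not retained: half-calls
are re-emitted as ``0/.`` on write.  No statistic in the package uses the
half-call allele, only the fact of the half-call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
HALF_CALL = 3
MISSING = -1

#: genotype codes that count as a fully called diploid genotype
CALLED_CODES = (HOM_REF, HET, HOM_ALT)

SAMPLE_SHEET_COLUMNS = ("sample", "sex", "species", "population")


def to_one_based(pos0):
    """0-based coordinate -> 1-based (VCF) coordinate."""
    return np.asarray(pos0) + 1


def to_zero_based(pos1):
    """1-based (VCF) coordinate -> 0-based internal coordinate."""
    return np.asarray(pos1) - 1


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample metadata: id, sex, species, population.

    Sample ids must be unique and sex must be ``male`` or ``female`` for every
    sample; all per-group statistics are driven by this table.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        self.frame = self.frame.loc[:, list(SAMPLE_SHEET_COLUMNS)].reset_index(drop=True)
        if self.frame["sample"].duplicated().any():
            dups = self.frame.loc[self.frame["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids in sheet: {dups}")
        bad_sex = set(self.frame["sex"].astype(str)) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"sex must be 'male' or 'female', got {sorted(bad_sex)}")

    @property
    def samples(self) -> list[str]:
        return self.frame["sample"].tolist()

    @property
    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species"]))

    def select(
        self,
        sex: str | None = None,
        species: str | Iterable[str] | None = None,
        population: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given labels (None = no constraint)."""
        mask = np.ones(len(self.frame), dtype=bool)
        if sex is not None:
            mask &= (self.frame["sex"] == sex).to_numpy()
        if species is not None:
            if isinstance(species, str):
                species = [species]
            mask &= self.frame["species"].isin(list(species)).to_numpy()
        if population is not None:
            mask &= (self.frame["population"] == population).to_numpy()
        return self.frame.loc[mask, "sample"].tolist()

    def sex_of(self, sample: str) -> str:
        row = self.frame.loc[self.frame["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in sheet")
        return str(row["sex"].iloc[0])

    @classmethod
    def read(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Biallelic SNP sites x samples with genotypes, depth and haplotypes.

    Attributes
    ----------
    chrom, pos, ref, alt, qual
        Per-site arrays; ``pos`` is 1-based and strictly increasing within a
        chromosome.
    gt
        ``(n_sites, n_samples)`` int8 genotype codes (module constants).
    depth
        ``(n_sites, n_samples)`` int32 read depth, ``-1`` when absent.
    haplotypes
        Optional ``(n_sites, n_samples, 2)`` int8 phased alleles (0/1, -1
        missing); present only when every heterozygous call was phased.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    samples: list[str]
    gt: np.ndarray
    depth: np.ndarray
    haplotypes: np.ndarray | None = None
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = self.pos.shape[0]
        if self.gt.shape != (n, len(self.samples)):
            raise ValueError("gt shape does not match sites x samples")
        if self.depth.shape != self.gt.shape:
            raise ValueError("depth shape does not match gt")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.chrom.tolist()))

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([idx[s] for s in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype table") from None

    def sites_on(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def subset_sites(self, index) -> "GenotypeTable":
        """New table restricted to a boolean mask or index array over sites.

        An all-True boolean mask returns a shallow copy sharing the arrays
        (callers that mutate copy first).
        """
        if isinstance(index, np.ndarray) and index.dtype == bool and index.all():
            return replace(self)
        haps = None if self.haplotypes is None else self.haplotypes[index]
        return GenotypeTable(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=self.qual[index],
            samples=list(self.samples),
            gt=self.gt[index],
            depth=self.depth[index],
            haplotypes=haps,
        )

    def validate_sorted(self) -> None:
        """Raise if positions are not strictly increasing within chromosomes."""
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")


def read_vcf(path, sample_sheet: SampleSheet | None = None) -> GenotypeTable:
    """Read a VCF (v4.2, GT and optionally DP) into a :class:`GenotypeTable`.

    Multiallelic and non-SNP records are skipped and counted in
    ``n_skipped_records``.  Sample columns are reordered to match the sheet;
    a sheet sample absent from the VCF is an error.  Phased GT separators are
    preserved into the haplotype matrix when every het call is phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    if sample_sheet is not None:
        missing = [s for s in sample_sheet.samples if s not in vcf_samples]
        if missing:
            raise ValueError(f"samples in sheet absent from VCF: {missing}")
        order = [vcf_samples.index(s) for s in sample_sheet.samples]
        samples = sample_sheet.samples
    else:
        order = list(range(len(vcf_samples)))
        samples = vcf_samples

    chrom, pos, ref, alt, qual = [], [], [], [], []
    gt_rows, dp_rows, hap_rows = [], [], []
    n_skipped = 0
    all_phased = True

    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        genos = var.genotypes
        row_gt = np.empty(len(order), dtype=np.int8)
        row_hap = np.full((len(order), 2), MISSING, dtype=np.int8)
        for out_j, j in enumerate(order):
            g = genos[j]
            if len(g) == 2:  # haploid call, emitted by some callers
                a0 = a1 = g[0]
                phased = True
            else:
                a0, a1, phased = g[0], g[1], bool(g[2])
            called = (a0 >= 0) + (a1 >= 0)
            if called == 2:
                row_gt[out_j] = HET if a0 != a1 else (HOM_REF if a0 == 0 else HOM_ALT)
                if row_gt[out_j] == HET and not phased:
                    all_phased = False
            elif called == 1:
                row_gt[out_j] = HALF_CALL
            else:
                row_gt[out_j] = MISSING
            row_hap[out_j, 0] = a0
            row_hap[out_j, 1] = a1
        dp = var.format("DP")
        if dp is not None:
            row_dp = dp[:, 0].astype(np.int32)[order]
            row_dp[row_dp < 0] = -1
        else:
            row_dp = np.full(len(order), -1, dtype=np.int32)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        qual.append(var.QUAL if var.QUAL is not None else np.nan)
        gt_rows.append(row_gt)
        dp_rows.append(row_dp)
        hap_rows.append(row_hap)

    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    n = len(pos)
    table = GenotypeTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        samples=list(samples),
        gt=np.array(gt_rows, dtype=np.int8).reshape(n, len(samples)),
        depth=np.array(dp_rows, dtype=np.int32).reshape(n, len(samples)),
        haplotypes=np.array(hap_rows, dtype=np.int8).reshape(n, len(samples), 2)
        if all_phased and n
        else None,
        n_skipped_records=n_skipped,
    )
    return table


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a :class:`GenotypeTable` as an uncompressed VCF v4.2 (GT:DP)."""
    n, m = table.n_sites, table.n_samples
    if table.haplotypes is not None:
        achar = np.array([".", "0", "1"], dtype="U1")
        a0 = achar[table.haplotypes[:, :, 0].astype(np.int16) + 1]
        a1 = achar[table.haplotypes[:, :, 1].astype(np.int16) + 1]
        gt_str = np.char.add(np.char.add(a0, "|"), a1)
    else:
        lut = np.array(["./.", "0/0", "0/1", "1/1", "0/."], dtype="U3")
        gt_str = lut[table.gt.astype(np.int16) + 1]
    dp_str = table.depth.astype("U12")
    dp_str[table.depth < 0] = "."
    cells = np.char.add(np.char.add(gt_str, ":"), dp_str)

    qual_str = np.where(np.isnan(table.qual), ".", np.char.mod("%g", table.qual))
    body = pd.DataFrame(
        {
            "#CHROM": table.chrom,
            "POS": table.pos,
            "ID": ".",
            "REF": table.ref,
            "ALT": table.alt,
            "QUAL": qual_str,
            "FILTER": ".",
            "INFO": ".",
            "FORMAT": "GT:DP",
        }
    )
    for j, s in enumerate(table.samples):
        body[s] = cells[:, j] if n else []

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in table.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        body.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Half-open genomic windows tiling chromosomes."""

    frame: pd.DataFrame  # columns: chrom, start, end (0-based half-open)
    size: int
    step: int

    @property
    def n(self) -> int:
        return len(self.frame)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def write_bed(self, path) -> None:
        self.frame.to_csv(path, sep="\t", header=False, index=False)


def make_windows(chrom_lengths: Mapping[str, int], size: int, step: int | None = None) -> WindowSet:
    """Tile each chromosome with half-open [start, end) windows.

    The last window is truncated at the chromosome end.  ``step`` defaults to
    ``size`` (non-overlapping); ``size < step`` (gapped tiling) is an error.
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if size < step:
        raise ValueError("size < step would leave gaps between windows")
    rows = []
    for c, length in chrom_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {c} has non-positive length")
        start = 0
        while start < length:
            rows.append((c, start, min(start + size, length)))
            start += step
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return WindowSet(frame=frame, size=size, step=step)


def window_site_ranges(table: GenotypeTable, windows: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (lo, hi) site-index ranges into the table.

    Sites inside window w are ``table`` rows ``lo[w]:hi[w]``.  Requires sites
    sorted by position within chromosomes (the table invariant).  Works for
    overlapping windows too since each window gets its own searchsorted range.
    """
    lo = np.empty(windows.n, dtype=np.int64)
    hi = np.empty(windows.n, dtype=np.int64)
    pos0 = table.pos - 1  # windows are 0-based half-open
    offsets = {}
    for c in table.chromosomes:
        mask = table.chrom == c
        offsets[c] = (np.flatnonzero(mask)[0], pos0[mask])
    for w, (c, start, end) in enumerate(
        windows.frame[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if c not in offsets:
            lo[w] = hi[w] = 0
            continue
        off, p = offsets[c]
        lo[w] = off + np.searchsorted(p, start, side="left")
        hi[w] = off + np.searchsorted(p, end, side="left")
    return lo, hi


def windowed_sums(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sum per-site values over windows given (lo, hi) ranges.

    ``values`` has sites on axis 0; returns an array with windows on axis 0.
    Uses a cumulative sum so overlapping windows cost the same as disjoint.
    """
    values = np.asarray(values)
    n = values.shape[0]
    shape = (lo.shape[0],) + values.shape[1:]
    if n == 0 or lo.shape[0] == 0:
        return np.zeros(shape)
    contiguous = (
        np.all(hi[:-1] == lo[1:]) if lo.shape[0] > 1 else True
    ) and lo[0] == 0 and hi[-1] == n and np.all(hi >= lo)
    if contiguous:
        # non-overlapping tiling: one reduceat pass
        if values.dtype == bool:
            acc = values.astype(np.int32)
        elif values.dtype.kind in "iu":
            acc = values.astype(np.int64, copy=False)
        else:
            acc = values.astype(np.float64, copy=False)
        starts = np.minimum(lo, n - 1)
        out = np.add.reduceat(acc, starts, axis=0).astype(np.float64)
        out[lo == hi] = 0.0  # reduceat yields values[lo] for empty ranges
        return out
    c = np.cumsum(values, axis=0, dtype=np.float64)
    top = np.where((hi > 0).reshape((-1,) + (1,) * (c.ndim - 1)), c[np.maximum(hi - 1, 0)], 0.0)
    bot = np.where((lo > 0).reshape((-1,) + (1,) * (c.ndim - 1)), c[np.maximum(lo - 1, 0)], 0.0)
    return top - bot
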