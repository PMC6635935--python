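"""Core domain types and file I/O.

Holds the four containers every downstream statistic operates on:

* :class:`Alignment` — a labelled matrix of aligned nucleotide sequences
  (e.g. the 1,646 bp COI+COII+Cyt b concatenation, or a 626 bp COI set).
* :class:`HaplotypeSpectrum` — a haplotype × population count table.
* :class:`GenotypeTable` — diploid fragment-length genotypes for codominant
  nuclear loci.
* :class:`Partition` — the two-level sampling hierarchy (individual → site,
  site → morphoclimatic region).

Readers/writers use plain FASTA and tab-separated text.  Sites containing
gaps or IUPAC ambiguity codes are removed alignment-wide (complete deletion)
before haplotype collapsing and all sequence statistics, so every count is
reproducible from the files alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Unambiguous nucleotide symbols kept by complete deletion.
CANONICAL_BASES = frozenset("ACGT")

#: Sentinel for a missing allele in genotype tables.
MISSING = -1


class AlignmentError(ValueError):
    """Raised for malformed alignments (length mismatch, duplicate ids)."""


class InputError(ValueError):
    """Raised for malformed input tables."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Aligned nucleotide sequences with per-individual population labels.

    Parameters
    ----------
    ids
        Unique individual identifiers, one per row.
    seqs
        ``(n, L)`` array of single uppercase IUPAC characters.
    pop_labels
        Per-individual sampling-site label.
    region_labels
        Per-individual morphoclimatic-region label.
    locus_bounds
        Optional ``{name: (start, end)}`` half-open intervals naming the
        loci of a concatenated alignment; must tile ``[0, L)``.
    """

    ids: list[str]
    seqs: np.ndarray
    pop_labels: list[str] | None = None
    region_labels: list[str] | None = None
    locus_bounds: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs)
        if self.seqs.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D (n x L)")
        n = len(self.ids)
        if self.seqs.shape[0] != n:
            raise AlignmentError(
                f"{n} ids but {self.seqs.shape[0]} sequence rows"
            )
        if len(set(self.ids)) != n:
            dups = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate ids: {dups}")
        if self.pop_labels is None:
            self.pop_labels = ["pop1"] * n
        if self.region_labels is None:
            self.region_labels = ["region1"] * n
        if len(self.pop_labels) != n or len(self.region_labels) != n:
            raise AlignmentError("label vectors must match number of ids")
        if self.locus_bounds is not None:
            self._check_locus_bounds()

    def _check_locus_bounds(self) -> None:
        ivals = sorted(self.locus_bounds.values())
        if ivals[0][0] != 0 or ivals[-1][1] != self.length:
            raise AlignmentError("locus bounds must tile [0, L)")
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            if e1 != s2:
                raise AlignmentError("locus bounds overlap or leave gaps")

    # -- basic properties --------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @classmethod
    def from_strings(
        cls,
        ids: Sequence[str],
        sequences: Sequence[str],
        pop_labels: Sequence[str] | None = None,
        region_labels: Sequence[str] | None = None,
        locus_bounds: dict[str, tuple[int, int]] | None = None,
    ) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        mat = np.array([list(s.upper()) for s in sequences], dtype="U1")
        if mat.size == 0:
            mat = mat.reshape(len(sequences), 0)
        return cls(
            ids=list(ids),
            seqs=mat,
            pop_labels=list(pop_labels) if pop_labels is not None else None,
            region_labels=list(region_labels) if region_labels is not None else None,
            locus_bounds=locus_bounds,
        )

    def sequence(self, i: int) -> str:
        return "".join(self.seqs[i])

    # -- views -------------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "Alignment":
        """Row subset (no locus bounds carried: they still apply)."""
        idx = np.flatnonzero(np.asarray(mask))
        return Alignment(
            ids=[self.ids[i] for i in idx],
            seqs=self.seqs[idx],
            pop_labels=[self.pop_labels[i] for i in idx],
            region_labels=[self.region_labels[i] for i in idx],
            locus_bounds=self.locus_bounds,
        )

    def population(self, label: str, by: str = "pop") -> "Alignment":
        labels = self.pop_labels if by == "pop" else self.region_labels
        mask = np.array([l == label for l in labels])
        if not mask.any():
            raise InputError(f"no individuals labelled {label!r}")
        return self.subset(mask)

    def clean_columns(self) -> np.ndarray:
        """Boolean mask of sites free of gaps/ambiguities in every sequence."""
        if self.n == 0:
            return np.zeros(self.length, dtype=bool)
        ok = np.isin(self.seqs, sorted(CANONICAL_BASES))
        return ok.all(axis=0)

    def complete_deletion(self) -> "Alignment":
        """Alignment restricted to unambiguous columns (locus bounds dropped)."""
        keep = self.clean_columns()
        return Alignment(
            ids=list(self.ids),
            seqs=self.seqs[:, keep],
            pop_labels=list(self.pop_labels),
            region_labels=list(self.region_labels),
        )


def read_fasta(path: str | Path, metadata: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Headers of the form ``id|site|region`` carry labels inline; a sidecar
    TSV with columns ``id``, ``site``, ``region`` may override them
    (sidecar wins on conflict).
    """
    ids: list[str] = []
    seqs: list[str] = []
    pops: list[str] = []
    regions: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        ids.append(parts[0])
        pops.append(parts[1] if len(parts) > 1 else "pop1")
        regions.append(parts[2] if len(parts) > 2 else "region1")
        seqs.append(str(rec.seq).upper())
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate ids in {path}")
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype=str)
        site_of = dict(zip(meta["id"], meta["site"]))
        region_of = dict(zip(meta["id"], meta["region"]))
        pops = [site_of.get(i, p) for i, p in zip(ids, pops)]
        regions = [region_of.get(i, r) for i, r in zip(ids, regions)]
    return Alignment.from_strings(ids, seqs, pops, regions)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(aln.sequence(i)),
            id=f"{aln.ids[i]}|{aln.pop_labels[i]}|{aln.region_labels[i]}",
            description="",
        )
        for i in range(aln.n)
    ]
    SeqIO.write(recs, str(path), "fasta")


def concatenate_loci(alignments: Sequence[Alignment],
                     names: Sequence[str] | None = None) -> Alignment:
    """Concatenate single-locus alignments over the same individuals.

    Individuals are matched by id; the row order of the first alignment is
    preserved.  Lengths add and ``locus_bounds`` records each input.
    """
    if not alignments:
        raise InputError("no alignments to concatenate")
    first = alignments[0]
    ref = set(first.ids)
    for a in alignments[1:]:
        if set(a.ids) != ref:
            missing = sorted(ref.symmetric_difference(a.ids))
            raise InputError(f"id sets differ between loci: {missing}")
    if names is None:
        names = [f"locus{i + 1}" for i in range(len(alignments))]
    blocks = [first.seqs]
    bounds: dict[str, tuple[int, int]] = {names[0]: (0, first.length)}
    offset = first.length
    for a, name in zip(alignments[1:], names[1:]):
        order = [a.ids.index(i) for i in first.ids]
        blocks.append(a.seqs[order])
        bounds[name] = (offset, offset + a.length)
        offset += a.length
    return Alignment(
        ids=list(first.ids),
        seqs=np.concatenate(blocks, axis=1),
        pop_labels=list(first.pop_labels),
        region_labels=list(first.region_labels),
        locus_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# HaplotypeSpectrum
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpectrum:
    """Haplotype × population count table.

    ``counts[i, j]`` is the number of copies of haplotype ``i`` in
    population ``j``.  Column sums are the per-population sample sizes.
    """

    haplotype_ids: list[str]
    counts: np.ndarray
    population_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise InputError("counts must be 2-D (haplotype x population)")
        if self.counts.shape != (len(self.haplotype_ids), len(self.population_ids)):
            raise InputError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise InputError("negative haplotype counts")
        if len(self.haplotype_ids) and (self.counts.sum(axis=1) == 0).any():
            raise InputError("all-zero haplotype row")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    def sample_size(self, population: str | None = None) -> int:
        return int(self.column(population).sum())

    def column(self, population: str | None = None) -> np.ndarray:
        """Counts for one population, or pooled over all (``None``)."""
        if population is None:
            return self.counts.sum(axis=1)
        try:
            j = self.population_ids.index(population)
        except ValueError:
            raise InputError(f"unknown population {population!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.haplotype_ids, columns=self.population_ids
        )


def collapse_haplotypes(aln: Alignment, by: str = "region") -> HaplotypeSpectrum:
    """Collapse identical sequences into haplotypes.

    Ambiguous/gapped columns are removed alignment-wide first.  Haplotype
    ids ``H1..Hk`` are assigned in descending total frequency, ties broken
    by first occurrence; counts are split by the chosen label (``"region"``,
    ``"pop"``, or ``"all"`` for a single pooled column).
    """
    if aln.n == 0:
        return HaplotypeSpectrum([], np.zeros((0, 0), dtype=int), [])
    clean = aln.complete_deletion()
    keys = ["".join(row) for row in clean.seqs]
    if by == "all":
        labels = ["all"] * aln.n
    elif by == "pop":
        labels = aln.pop_labels
    else:
        labels = aln.region_labels
    pops = list(dict.fromkeys(labels))
    first_seen: dict[str, int] = {}
    totals: dict[str, int] = {}
    for i, k in enumerate(keys):
        first_seen.setdefault(k, i)
        totals[k] = totals.get(k, 0) + 1
    order = sorted(totals, key=lambda k: (-totals[k], first_seen[k]))
    hap_index = {k: i for i, k in enumerate(order)}
    counts = np.zeros((len(order), len(pops)), dtype=int)
    pop_index = {p: j for j, p in enumerate(pops)}
    for k, lab in zip(keys, labels):
        counts[hap_index[k], pop_index[lab]] += 1
    ids = [f"H{i + 1}" for i in range(len(order))]
    return HaplotypeSpectrum(ids, counts, pops)


# Spectrum cell notation: "H1(3); H2(2); H3; H24-H28".  Accepts the unicode
# hyphen (U+2010) and en-dash that appear in published tables.
_DASHES = "-‐‑‒–"
_CELL_ITEM = re.compile(
    rf"^(?P<a>[A-Za-z0-9_.]+?)(?:[{_DASHES}](?P<b>[A-Za-z0-9_.]+?))?"
    rf"(?:\((?P<count>\d+)\))?$"
)


def _parse_cell(cell: str, row: str, col: str) -> dict[str, int]:
    """Parse one haplotype-list cell into {haplotype: count}."""
    out: dict[str, int] = {}
    cell = cell.strip()
    if not cell or cell in {".", "-"}:
        return out
    for item in re.split(r";\s*", cell):
        item = item.strip()
        if not item:
            continue
        m = _CELL_ITEM.match(item)
        if not m:
            raise InputError(f"malformed cell entry {item!r} at row {row!r}, column {col!r}")
        a, b, count = m.group("a"), m.group("b"), m.group("count")
        if b is not None:
            # a range like H24-H28 expands to singletons
            pa = re.match(r"^([A-Za-z_]*)(\d+)$", a)
            pb = re.match(r"^([A-Za-z_]*)(\d+)$", b)
            if not pa or not pb or pa.group(1) != pb.group(1):
                raise InputError(
                    f"malformed range {item!r} at row {row!r}, column {col!r}"
                )
            lo, hi = int(pa.group(2)), int(pb.group(2))
            if hi < lo:
                raise InputError(
                    f"descending range {item!r} at row {row!r}, column {col!r}"
                )
            for k in range(lo, hi + 1):
                out[f"{pa.group(1)}{k}"] = out.get(f"{pa.group(1)}{k}", 0) + 1
        else:
            out[a] = out.get(a, 0) + (int(count) if count else 1)
    return out


def read_haplotype_table(path: str | Path) -> HaplotypeSpectrum:
    """Read a haplotype spectrum from TSV.

    Two layouts are accepted: a wide numeric matrix (first column =
    haplotype id, remaining columns = per-population counts), or a
    "spectrum cell" layout with columns ``population`` and ``haplotypes``
    where each cell lists haplotypes in ``H1(3); H2; H24-H28`` notation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = [c.lower() for c in df.columns]
    if "haplotypes" in cols:
        popcol = df.columns[cols.index("population")]
        hapcol = df.columns[cols.index("haplotypes")]
        pops = list(df[popcol])
        per_pop = [
            _parse_cell(cell, pop, "haplotypes")
            for pop, cell in zip(pops, df[hapcol])
        ]
        all_haps: dict[str, int] = {}
        for d in per_pop:
            for h, c in d.items():
                all_haps[h] = all_haps.get(h, 0) + c
        order = sorted(all_haps, key=lambda h: (-all_haps[h], list(all_haps).index(h)))
        counts = np.array(
            [[d.get(h, 0) for d in per_pop] for h in order], dtype=int
        )
        return HaplotypeSpectrum(order, counts, pops)
    hap_ids = list(df.iloc[:, 0])
    pops = list(df.columns[1:])
    try:
        counts = df.iloc[:, 1:].replace("", "0").astype(int).to_numpy()
    except ValueError as exc:
        raise InputError(f"non-integer count in {path}: {exc}") from None
    keep = counts.sum(axis=1) > 0
    return HaplotypeSpectrum(
        [h for h, k in zip(hap_ids, keep) if k], counts[keep], pops
    )


def write_haplotype_table(spec: HaplotypeSpectrum, path: str | Path) -> None:
    spec.to_frame().rename_axis("haplotype").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid fragment-length genotypes for codominant nuclear loci.

    ``genotypes[i, l]`` is the unordered allele-size pair (stored sorted)
    of individual ``i`` at locus ``l``; missing alleles are ``-1``.
    """

    ids: list[str]
    loci: list[str]
    genotypes: np.ndarray  # (n, n_loci, 2) int
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        n, nl = len(self.ids), len(self.loci)
        if self.genotypes.shape != (n, nl, 2):
            raise InputError(
                f"genotype array shape {self.genotypes.shape} != ({n}, {nl}, 2)"
            )
        if len(self.pop_labels) != n:
            raise InputError("pop_labels length mismatch")
        valid = self.genotypes != MISSING
        if (self.genotypes[valid] <= 0).any():
            raise InputError("allele sizes must be positive integers")
        # unordered storage: sort each pair, missing (-1) first
        self.genotypes = np.sort(self.genotypes, axis=2)

    @property
    def n(self) -> int:
        return len(self.ids)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise InputError(f"unknown locus {locus!r}") from None

    def population_mask(self, population: str | None) -> np.ndarray:
        if population is None:
            return np.ones(self.n, dtype=bool)
        mask = np.array([p == population for p in self.pop_labels])
        if not mask.any():
            raise InputError(f"no individuals in population {population!r}")
        return mask

    def alleles_at(self, locus: str, population: str | None = None) -> np.ndarray:
        """Non-missing allele sizes (gene copies) at a locus."""
        g = self.genotypes[self.population_mask(population), self.locus_index(locus)]
        complete = (g != MISSING).all(axis=1)
        return g[complete].ravel()

    def complete_genotypes(self, locus: str, population: str | None = None) -> np.ndarray:
        """(m, 2) array of fully typed genotypes at a locus."""
        g = self.genotypes[self.population_mask(population), self.locus_index(locus)]
        return g[(g != MISSING).all(axis=1)]


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read genotypes from TSV: columns ``id``, ``population``, then one
    column per locus holding ``a/b`` (allele sizes) or ``.`` for missing."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    if df.columns[0].lower() != "id" or df.columns[1].lower() != "population":
        raise InputError("genotype table must start with 'id' and 'population' columns")
    loci = list(df.columns[2:])
    n = len(df)
    geno = np.full((n, len(loci), 2), MISSING, dtype=int)
    for l, locus in enumerate(loci):
        for i, cell in enumerate(df[locus]):
            cell = cell.strip()
            if cell in {".", "", "-", "./."}:
                continue
            try:
                a, b = cell.split("/")
                geno[i, l] = (int(a), int(b))
            except ValueError:
                raise InputError(
                    f"malformed genotype {cell!r} at row {i}, locus {locus}"
                ) from None
    return GenotypeTable(list(df.iloc[:, 0]), loci, geno, list(df.iloc[:, 1]))


def write_genotype_table(gt: GenotypeTable, path: str | Path) -> None:
    rows = []
    for i in range(gt.n):
        row: dict[str, str] = {"id": gt.ids[i], "population": gt.pop_labels[i]}
        for l, locus in enumerate(gt.loci):
            a, b = gt.genotypes[i, l]
            row[locus] = "." if a == MISSING or b == MISSING else f"{a}/{b}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Two-level sampling hierarchy: individual → site, site → region."""

    site_of: dict[str, str]
    region_of_site: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sites = set(self.site_of.values())
        if self.region_of_site:
            missing = sites - set(self.region_of_site)
            if missing:
                raise InputError(f"sites without a region: {sorted(missing)}")

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "Partition":
        site_of = dict(zip(aln.ids, aln.pop_labels))
        region_of: dict[str, str] = {}
        for site, region in zip(aln.pop_labels, aln.region_labels):
            prev = region_of.setdefault(site, region)
            if prev != region:
                raise InputError(f"site {site!r} mapped to two regions")
        return cls(site_of, region_of)

    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.site_of.values()))

    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.region_of_site.values()))

    def site_labels(self, ids: Sequence[str]) -> list[str]:
        try:
            return [self.site_of[i] for i in ids]
        except KeyError as exc:
            raise InputError(f"individual {exc.args[0]!r} not in partition") from None

    def region_labels(self, ids: Sequence[str]) -> list[str]:
        return [self.region_of_site[self.site_of[i]] for i in ids]
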