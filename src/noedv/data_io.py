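"""Genotype/phenotype tables and effect lists: containers, readers, writers.

Genotypes are coded 0 (homozygous common), 1 (heterozygous), 2 (homozygous
minor); the phenotype is 0 (control) / 1 (case).  SNP indices are 1-based in
every user-facing structure, matching the usual convention for SNP panels.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePhenotypeError,
    FormatError,
    MalformedGenotypeError,
    MalformedPhenotypeError,
    ReferenceError_,
)

__all__ = [
    "GenotypeDataset",
    "EffectRecord",
    "read_genotype_table",
    "write_genotype_table",
    "read_effect_list",
    "write_effect_list",
    "default_snp_names",
]

_PHENO_NAMES = ("class", "Class", "CLASS")


def default_snp_names(n: int) -> list[str]:
    return [f"SNP{i}" for i in range(1, n + 1)]


@dataclasses.dataclass(frozen=True)
class GenotypeDataset:
    """An M x N genotype matrix with a binary case/control phenotype.

    Validates on construction: every genotype cell must lie in {0, 1, 2},
    every phenotype entry in {0, 1}, both classes must be present, and SNP
    names must be unique.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: tuple[str, ...] = ()

    def __post_init__(self):
        geno = np.asarray(self.genotypes)
        pheno = np.asarray(self.phenotype)
        if geno.ndim != 2:
            raise FormatError("genotype matrix must be two-dimensional")
        if pheno.ndim != 1 or pheno.shape[0] != geno.shape[0]:
            raise FormatError(
                f"phenotype length {pheno.shape} does not match {geno.shape[0]} individuals"
            )
        names = tuple(self.snp_names) or tuple(default_snp_names(geno.shape[1]))
        if len(names) != geno.shape[1]:
            raise FormatError("snp_names length does not match SNP count")
        if len(set(names)) != len(names):
            raise FormatError("snp_names must be unique")

        if not np.issubdtype(geno.dtype, np.integer):
            flt = np.asarray(geno, dtype=float)
            geno_int = flt.astype(np.int64)
            if not np.array_equal(flt, geno_int):
                bad = np.argwhere(flt != geno_int)[0]
                raise MalformedGenotypeError(int(bad[0]) + 1, names[int(bad[1])], flt[tuple(bad)])
            geno = geno_int
        bad_mask = (geno < 0) | (geno > 2)
        if bad_mask.any():
            r, c = np.argwhere(bad_mask)[0]
            raise MalformedGenotypeError(int(r) + 1, names[int(c)], geno[r, c])

        if not np.issubdtype(pheno.dtype, np.integer):
            flt = np.asarray(pheno, dtype=float)
            pheno = flt.astype(np.int64)
            if not np.array_equal(flt, pheno):
                raise MalformedPhenotypeError("phenotype entries must be integers 0/1")
        if np.any((pheno < 0) | (pheno > 1)):
            raise MalformedPhenotypeError("phenotype entries must be 0 (control) or 1 (case)")
        if geno.shape[0] < 2:
            raise FormatError("at least two individuals are required")
        if pheno.min() == pheno.max():
            raise DegeneratePhenotypeError(
                "phenotype contains a single class; both cases and controls are required"
            )

        object.__setattr__(self, "genotypes", np.ascontiguousarray(geno, dtype=np.int8))
        object.__setattr__(self, "phenotype", np.ascontiguousarray(pheno, dtype=np.int8))
        object.__setattr__(self, "snp_names", names)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def column(self, snp: int) -> np.ndarray:
        """Genotype column of a 1-based SNP index."""
        if not 1 <= snp <= self.n_snps:
            raise IndexError(f"SNP index {snp} outside [1, {self.n_snps}]")
        return self.genotypes[:, snp - 1]

    def name_to_index(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.snp_names)}


@dataclasses.dataclass(frozen=True, order=True)
class EffectRecord:
    """One scored SNP combination: the unit of rankings and hypergraphs.

    ``snps`` is a sorted tuple of distinct 1-based indices; ``order`` equals
    its length.  ``ci`` is the co-information in bits, ``nci`` the
    order-normalized effect, ``cci`` the optional cumulative effect.
    """

    snps: tuple[int, ...]
    order: int
    ci: float
    nci: float
    cci: float | None = None

    def __post_init__(self):
        snps = tuple(int(s) for s in self.snps)
        if len(snps) == 0:
            raise ValueError("empty SNP combination")
        if any(s < 1 for s in snps):
            raise ValueError(f"SNP indices must be >= 1, got {snps}")
        if len(set(snps)) != len(snps):
            raise ValueError(f"duplicate SNP indices in {snps}")
        if tuple(sorted(snps)) != snps:
            raise ValueError(f"SNP tuple must be sorted ascending, got {snps}")
        if self.order != len(snps):
            raise ValueError(f"order {self.order} != {len(snps)} indices")
        object.__setattr__(self, "snps", snps)


def _detect_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _read_table(path: Path) -> pd.DataFrame:
    sep = _detect_delimiter(path)
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _parse_genotype_frame(frame: pd.DataFrame) -> np.ndarray:
    names = list(frame.columns)
    geno = np.empty(frame.shape, dtype=np.int8)
    for j, col in enumerate(names):
        raw = frame[col].to_numpy()
        for i, cell in enumerate(raw):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise MalformedGenotypeError(i + 1, col, cell) from None
            if v not in (0, 1, 2):
                raise MalformedGenotypeError(i + 1, col, cell)
            geno[i, j] = v
    return geno


def _parse_phenotype(values: Iterable[object]) -> np.ndarray:
    out = []
    for cell in values:
        try:
            v = int(cell)
        except (TypeError, ValueError):
            raise MalformedPhenotypeError(f"phenotype value {cell!r} is not 0/1") from None
        if v not in (0, 1):
            raise MalformedPhenotypeError(f"phenotype value {cell!r} is not 0/1")
        out.append(v)
    return np.asarray(out, dtype=np.int8)


def read_genotype_table(
    path: str | Path,
    dialect: str = "combined",
    phenotype_path: str | Path | None = None,
) -> GenotypeDataset:
    """Read a delimited genotype table (comma or tab, auto-detected).

    ``combined``: one table whose last column, named ``class``, is the
    phenotype.  ``split``: genotypes in ``path``, the phenotype as a
    single-column file at ``phenotype_path``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "combined":
        frame = _read_table(path)
        pheno_col = next((c for c in frame.columns if c in _PHENO_NAMES), None)
        if pheno_col is None:
            raise FormatError(f"no phenotype column named one of {_PHENO_NAMES} in {path}")
        pheno = _parse_phenotype(frame[pheno_col].to_numpy())
        geno_frame = frame.drop(columns=[pheno_col])
    elif dialect == "split":
        if phenotype_path is None:
            raise FormatError("split dialect requires phenotype_path")
        geno_frame = _read_table(path)
        pheno_frame = _read_table(Path(phenotype_path))
        if pheno_frame.shape[1] != 1:
            raise FormatError("phenotype file must contain exactly one column")
        pheno = _parse_phenotype(pheno_frame.iloc[:, 0].to_numpy())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    geno = _parse_genotype_frame(geno_frame)
    return GenotypeDataset(geno, pheno, tuple(str(c) for c in geno_frame.columns))


def write_genotype_table(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the combined-dialect table (comma-delimited, phenotype column 'class')."""
    frame = pd.DataFrame(dataset.genotypes, columns=list(dataset.snp_names))
    frame["class"] = dataset.phenotype
    frame.to_csv(path, index=False)


_EFFECT_HEADER = ["snps", "order", "ci", "nci", "cci"]


def write_effect_list(
    records: Sequence[EffectRecord],
    path: str | Path,
    snp_names: Sequence[str] | None = None,
) -> None:
    """Write records as delimited text: snps (colon-joined names), order, ci, nci, cci.

    Floats are written with ``repr`` so a read-back restores full precision.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EFFECT_HEADER)
        for rec in records:
            if snp_names is not None:
                label = ":".join(snp_names[s - 1] for s in rec.snps)
            else:
                label = ":".join(f"SNP{s}" for s in rec.snps)
            writer.writerow(
                [
                    label,
                    rec.order,
                    repr(float(rec.ci)),
                    repr(float(rec.nci)),
                    "" if rec.cci is None else repr(float(rec.cci)),
                ]
            )


def read_effect_list(
    path: str | Path,
    snp_names: Sequence[str] | None = None,
) -> list[EffectRecord]:
    """Inverse of :func:`write_effect_list`.

    SNP names are resolved against ``snp_names`` when given; otherwise names
    must follow the default ``SNP<k>`` pattern, whose number is the index.
    """
    lookup: Mapping[str, int] | None = None
    if snp_names is not None:
        lookup = {name: i + 1 for i, name in enumerate(snp_names)}
    records: list[EffectRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _EFFECT_HEADER:
            raise FormatError(f"effect list {path} lacks the expected header {_EFFECT_HEADER}")
        for row in reader:
            if not row:
                continue
            names = row[0].split(":")
            idx = []
            for name in names:
                if lookup is not None:
                    if name not in lookup:
                        raise ReferenceError_(f"unknown SNP name {name!r} in {path}")
                    idx.append(lookup[name])
                else:
                    m = re.fullmatch(r"SNP(\d+)", name)
                    if not m:
                        raise ReferenceError_(
                            f"SNP name {name!r} does not follow the default SNP<k> pattern"
                        )
                    idx.append(int(m.group(1)))
            snps = tuple(sorted(idx))
            cci = None if row[4] == "" else float(row[4])
            records.append(
                EffectRecord(snps=snps, order=int(row[1]), ci=float(row[2]), nci=float(row[3]), cci=cci)
            )
    return records
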