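"""Readers and writers for every on-disk format the pipeline touches.

Formats: whitespace-delimited PED/MAP genotype text (two allele columns per
SNP), ADMIXTURE-style ``.Q`` ancestry matrices with an id/group sidecar,
tab-delimited association/trajectory tables, and one-id-per-line candidate
SNP lists.  All readers validate strictly and raise :class:`GioError` with
the offending SNP/row and line number rather than silently coercing.

Allele orientation: PED carries no designated reference allele, so the effect
allele of each SNP is defined as the *first* non-missing allele encountered
for that SNP in file order, and is recorded in ``snp_meta``; every downstream
effect estimate and frequency is reported relative to it.  Writers emit the
dataset's recorded alleles, so a round trip reproduces the dosages whenever
the first written genotype carries the effect allele (a known orientation
convention, not a data loss).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AncestryMatrix, GenotypeDataset

__all__ = [
    "GioError",
    "read_ped_map",
    "write_ped_map",
    "read_q",
    "write_q",
    "read_candidates",
    "write_assoc_table",
    "read_assoc_table",
]

logger = logging.getLogger(__name__)

ASSOC_TABLE_COLUMNS = [
    "snp",
    "effect_allele",
    "beta",
    "se",
    "p",
    "freq_g1",
    "freq_g2",
    "freq_g3",
    "class",
    "combined_p",
]


class GioError(ValueError):
    """Malformed input file."""


def _tokenize(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if toks:
                out.append((lineno, toks))
    return out


# --------------------------------------------------------------------------
# PED / MAP
# --------------------------------------------------------------------------

def read_ped_map(
    ped_path,
    map_path,
    info_path=None,
    allowed_alleles: str = "ACGT0",
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    PED columns: family id, individual id, father, mother, sex (1=M, 2=F,
    other=unknown), phenotype, then two allele columns per SNP; ``0 0`` allele
    pairs are missing genotypes.  MAP columns: chromosome, snp id, genetic
    distance, position.  The family-id column is kept as the recruitment
    center label.  ``info_path`` optionally points to a tab-delimited sidecar
    (columns ``id, sex, age, group, center``) carrying the metadata PED cannot
    hold; it overrides the PED-derived sex/center.
    """
    map_rows = _tokenize(map_path)
    snps, chroms, poss = [], [], []
    for lineno, toks in map_rows:
        if len(toks) < 4:
            raise GioError(f"{map_path}: line {lineno}: expected 4 MAP columns")
        chroms.append(toks[0])
        snps.append(toks[1])
        poss.append(int(toks[3]))
    if len(set(snps)) != len(snps):
        raise GioError(f"{map_path}: duplicate SNP ids")
    m = len(snps)

    allowed = set(allowed_alleles)
    # first-seen / second-seen allele per SNP, in file order
    allele1: list[str | None] = [None] * m
    allele2: list[str | None] = [None] * m

    ped_rows = _tokenize(ped_path)
    n = len(ped_rows)
    dosage_alleles: list[list[tuple[str, str]]] = []
    fams, iids, sexes = [], [], []
    for lineno, toks in ped_rows:
        if len(toks) != 6 + 2 * m:
            raise GioError(
                f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                f"({m} SNPs), got {len(toks)}"
            )
        fams.append(toks[0])
        iids.append(toks[1])
        sexes.append({"1": "M", "2": "F"}.get(toks[4]))
        pairs = []
        for k in range(m):
            a, b = toks[6 + 2 * k], toks[7 + 2 * k]
            for al in (a, b):
                if al not in allowed:
                    raise GioError(
                        f"{ped_path}: line {lineno}: SNP {snps[k]}: "
                        f"allele {al!r} not in allowed set {allowed_alleles!r}"
                    )
            if (a == "0") != (b == "0"):
                raise GioError(
                    f"{ped_path}: line {lineno}: SNP {snps[k]}: "
                    f"half-missing genotype {a} {b}"
                )
            for al in (a, b):
                if al == "0":
                    continue
                if allele1[k] is None:
                    allele1[k] = al
                elif al != allele1[k] and allele2[k] is None:
                    allele2[k] = al
                elif al not in (allele1[k], allele2[k]):
                    raise GioError(
                        f"{ped_path}: line {lineno}: SNP {snps[k]}: "
                        f"third allele {al!r} (triallelic)"
                    )
            pairs.append((a, b))
        dosage_alleles.append(pairs)
    if len(set(iids)) != len(iids):
        raise GioError(f"{ped_path}: duplicate individual ids")

    dosages = np.full((n, m), np.nan)
    for i, pairs in enumerate(dosage_alleles):
        for k, (a, b) in enumerate(pairs):
            if a == "0":
                continue
            dosages[i, k] = (a == allele1[k]) + (b == allele1[k])

    snp_meta = pd.DataFrame(
        {
            "snp": snps,
            "chrom": chroms,
            "pos": poss,
            "effect_allele": [a if a is not None else "0" for a in allele1],
            "other_allele": [a if a is not None else "0" for a in allele2],
        }
    )
    ind_meta = pd.DataFrame(
        {
            "id": iids,
            "sex": sexes,
            "age": np.nan,
            "group": "none",
            "center": fams,
        }
    )
    ds = GenotypeDataset(dosages, snp_meta, ind_meta)
    if info_path is not None:
        info = pd.read_csv(info_path, sep="\t", dtype={"id": str})
        missing_cols = {"id", "sex", "age", "group", "center"} - set(info.columns)
        if missing_cols:
            raise GioError(f"{info_path}: missing columns {sorted(missing_cols)}")
        info = info.set_index("id")
        unknown = [i for i in iids if i not in info.index]
        if unknown:
            raise GioError(f"{info_path}: no metadata for individual {unknown[0]!r}")
        aligned = info.loc[iids].reset_index()
        ds = GenotypeDataset(dosages, snp_meta, aligned[ds.ind_meta.columns])
    return ds


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path, info_path=None) -> None:
    """Write a dataset as PED/MAP (and optionally the metadata sidecar).

    The family-id column carries the recruitment-center label; phenotype is
    written as ``-9`` (the age-group design does not fit a single PED column,
    hence the sidecar).
    """
    sm = dataset.snp_meta
    with open(map_path, "w") as fh:
        for _, row in sm.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")
    sex_code = {"F": "2", "M": "1"}
    ea = sm["effect_allele"].to_numpy()
    oa = sm["other_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, row in dataset.ind_meta.iterrows():
            fields = [
                str(row["center"]),
                str(row["id"]),
                "0",
                "0",
                sex_code.get(row["sex"], "0"),
                "-9",
            ]
            for k in range(dataset.n_snps):
                d = dataset.dosages[i, k]
                if not np.isfinite(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [ea[k], ea[k]]
                elif d == 1:
                    fields += [ea[k], oa[k]]
                else:
                    fields += [oa[k], oa[k]]
            fh.write("\t".join(fields) + "\n")
    if info_path is not None:
        dataset.ind_meta.to_csv(info_path, sep="\t", index=False, float_format="%.12g")


# --------------------------------------------------------------------------
# ADMIXTURE-style Q matrices
# --------------------------------------------------------------------------

def read_q(q_path, ids_path) -> AncestryMatrix:
    """Read a whitespace ``.Q`` matrix plus an id (and optional group) sidecar.

    Rows must be non-negative and sum to 1 within 1e-4; they are renormalized
    exactly on read.  The sidecar has one row per individual: ``id`` or
    ``id group``.
    """
    rows = []
    for lineno, toks in _tokenize(q_path):
        try:
            vals = [float(t) for t in toks]
        except ValueError as exc:
            raise GioError(f"{q_path}: line {lineno}: non-numeric entry") from exc
        rows.append((lineno, vals))
    if not rows:
        raise GioError(f"{q_path}: empty ancestry matrix")
    k = len(rows[0][1])
    mat = np.empty((len(rows), k))
    for i, (lineno, vals) in enumerate(rows):
        if len(vals) != k:
            raise GioError(f"{q_path}: line {lineno}: expected {k} components")
        v = np.asarray(vals)
        if np.any(v < 0):
            raise GioError(f"{q_path}: row {i} (line {lineno}): negative fraction")
        s = v.sum()
        if not 0.999 <= s <= 1.001:
            raise GioError(
                f"{q_path}: row {i} (line {lineno}): fractions sum to {s:.6f}"
            )
        mat[i] = v / s

    ids, groups = [], []
    for lineno, toks in _tokenize(ids_path):
        ids.append(toks[0])
        groups.append(toks[1] if len(toks) > 1 else "none")
    if len(ids) != len(rows):
        raise GioError(
            f"{ids_path}: {len(ids)} ids for {len(rows)} ancestry rows"
        )
    return AncestryMatrix(mat, ids=ids, groups=groups)


def write_q(anc: AncestryMatrix, q_path, ids_path) -> None:
    np.savetxt(q_path, anc.proportions, fmt="%.6f")
    groups = anc.groups if anc.groups is not None else ["none"] * anc.n_individuals
    with open(ids_path, "w") as fh:
        for i, g in zip(anc.ids, groups):
            fh.write(f"{i}\t{g}\n")


# --------------------------------------------------------------------------
# candidate lists and result tables
# --------------------------------------------------------------------------

def read_candidates(path) -> list[str]:
    """Read a candidate SNP list: one id per line, ``#`` comments ignored.

    Duplicates are rejected; an empty file yields an empty list with a logged
    warning.
    """
    ids: list[str] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split("#", 1)[0].strip()
            if not tok:
                continue
            if tok in seen:
                raise GioError(f"{path}: line {lineno}: duplicate candidate id {tok!r}")
            seen.add(tok)
            ids.append(tok)
    if not ids:
        logger.warning("candidate file %s is empty", path)
    return ids


def write_assoc_table(records: pd.DataFrame, path) -> None:
    """Write a results table as TSV, lossless to 12 significant digits."""
    records.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_assoc_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
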