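"""Readers and writers for the plain-text formats used across the pipeline.

GENEPOP files carry diploid microsatellite genotypes with 3-digit allele
codes ("000" = missing), ESRI ASCII grids carry landscape rasters, and
delimited tables carry detection histories and distance matrices.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MultilocusGenotype

MISSING_CODE = "000"


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def write_genepop(path: str | Path,
                  individuals: Iterable[MultilocusGenotype],
                  loci: Sequence[str],
                  title: str = "tigerscape export") -> None:
    """Write individuals as a GENEPOP file with 3-digit diploid codes.

    Individuals are grouped into ``Pop`` blocks by their ``locality`` label,
    in order of first appearance. Missing loci are written as ``000000``.
    """
    groups: dict[str, list[MultilocusGenotype]] = {}
    for ind in individuals:
        groups.setdefault(ind.locality or "pop1", []).append(ind)
    lines = [title]
    lines.extend(loci)
    for label, members in groups.items():
        lines.append("Pop")
        for ind in members:
            codes = []
            for locus in loci:
                pair = ind.loci.get(locus)
                if pair is None:
                    codes.append(MISSING_CODE * 2)
                else:
                    a, b = sorted(pair)
                    if a <= 0 or b <= 0 or a > 999 or b > 999:
                        raise ValueError(
                            f"allele out of 3-digit range at {locus}: {pair}")
                    codes.append(f"{a:03d}{b:03d}")
            lines.append(f"{ind.sample_id} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path: str | Path) -> tuple[list[MultilocusGenotype], list[str]]:
    """Parse a GENEPOP file; returns (individuals, locus names).

    Handles locus names listed one per line or comma-separated on one line,
    and both 2x3-digit (6 char) diploid codes. Population labels are taken
    from the last individual id of the preceding block header convention is
    ignored; blocks are simply labelled pop1..popN unless ids carry labels.
    """
    text = Path(path).read_text().strip().splitlines()
    if len(text) < 3:
        raise ValueError("truncated GENEPOP file")
    # locus names: everything between the title and the first 'Pop'
    loci: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        line = text[i].strip()
        if "," in line:
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        elif line:
            loci.append(line)
        i += 1
    individuals: list[MultilocusGenotype] = []
    pop_idx = 0
    for line in text[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in stripped:
            raise ValueError(f"malformed genotype line: {stripped!r}")
        name, geno = stripped.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"{name.strip()}: {len(codes)} genotypes for {len(loci)} loci")
        calls: dict[str, tuple[int, int] | None] = {}
        for locus, code in zip(loci, codes):
            if not re.fullmatch(r"\d{4}|\d{6}", code):
                raise ValueError(f"bad allele code {code!r} at {locus}")
            half = len(code) // 2
            a, b = int(code[:half]), int(code[half:])
            calls[locus] = None if a == 0 or b == 0 else (a, b)
        individuals.append(MultilocusGenotype(
            sample_id=name.strip(), locality=f"pop{pop_idx}", loci=calls))
    return individuals, loci


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: np.ndarray,
                     cell_size_km: float = 10.0,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid. NaN cells become NODATA."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    out = np.where(np.isnan(grid), nodata, grid)
    header = (f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
              f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
              f"cellsize {cell_size_km}\nNODATA_value {nodata:g}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; NODATA cells become NaN.

    Returns (array, header dict with ncols/nrows/cellsize/...).
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    arr = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    return arr, header


# ---------------------------------------------------------------------------
# Detection histories and matrices
# ---------------------------------------------------------------------------

def write_detection_table(path: str | Path, histories, covariates: pd.DataFrame | None = None) -> None:
    """Write detection histories (one row per grid) as a TSV.

    Replicate columns are ``rep1..repK`` with NA for unsurveyed replicates;
    covariate columns are appended when supplied.
    """
    max_rep = max((len(h.outcomes) for h in histories), default=0)
    rows = []
    for h in histories:
        row = {"grid_id": h.grid_id}
        for j in range(max_rep):
            v = h.outcomes[j] if j < len(h.outcomes) else None
            row[f"rep{j + 1}"] = "NA" if v is None else int(v)
        row["abundance_index"] = h.abundance_index
        rows.append(row)
    df = pd.DataFrame(rows)
    if covariates is not None:
        df = df.merge(covariates, on="grid_id", how="left")
    df.to_csv(path, sep="\t", index=False)


def write_matrix_csv(path: str | Path, labels: Sequence[str], values: np.ndarray) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float)
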