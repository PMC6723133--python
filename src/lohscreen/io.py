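"""Shared file I/O: TSV tables, BED gene maps, gene lists, GAF, YAML config.

All tabular output is UTF-8 TSV with a header row, "NA" for missing
values, and leading ``#`` comment lines recording the tool version and the
thresholds used to produce the file.  Gene coordinates are read from BED
(0-based half-open) and held internally 1-based inclusive.
"""

from __future__ import annotations

import importlib.metadata
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .pge import GeneLocus

__all__ = [
    "tool_version",
    "read_tsv",
    "write_tsv",
    "read_gene_list",
    "write_gene_list",
    "read_bed",
    "write_bed",
    "read_annotations",
    "read_gaf",
    "read_hierarchy",
    "read_fluctuation_counts",
    "load_config",
]


def tool_version() -> str:
    try:
        return importlib.metadata.version("lohscreen")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _header_lines(params: Mapping | None) -> list[str]:
    lines = [f"# lohscreen {tool_version()}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_tsv(df: pd.DataFrame, path: str | Path, params: Mapping | None = None) -> None:
    """Write a TSV with version/threshold comment header; missing -> NA."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       keep_default_na=True, **kwargs)


def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene list; blank lines and # comments ignored."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Read a 3-6 column BED into 1-based inclusive gene loci.

    Rows are sorted by (chromosome, start); a missing name column is
    filled from coordinates; duplicate names and malformed lines (with
    their line number) are errors.
    """
    loci: list[GeneLocus] = []
    names: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = stripped.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start0, end0 = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start0 < 0 or end0 <= start0:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start0}, {end0})")
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else \
            f"{chrom}:{start0}-{end0}"
        if name in names:
            raise ValueError(f"{path}:{lineno}: duplicate gene name {name!r}")
        names.add(name)
        loci.append(GeneLocus(name, chrom, start0 + 1, end0))
    loci.sort(key=lambda g: (g.chromosome, g.start, g.end))
    out = []
    idx: dict[str, int] = {}
    for g in loci:
        i = idx.get(g.chromosome, 0)
        idx[g.chromosome] = i + 1
        out.append(GeneLocus(g.gene_id, g.chromosome, g.start, g.end, index=i))
    return out


def write_bed(loci: Sequence[GeneLocus], path: str | Path) -> None:
    """Write loci as 6-column BED (0-based half-open, '.' strand)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in sorted(loci, key=lambda g: (g.chromosome, g.start, g.end)):
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t.\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (gene, term) -> gene -> term-set mapping."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns (gene, term)")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """GAF 2.x annotations: symbol (col 3), GO id (col 5), aspect kept
    implicit.  Comment lines (``!``) are skipped."""
    mapping: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 15:
            continue
        symbol, go_id = fields[2], fields[4]
        if symbol and go_id:
            mapping.setdefault(symbol, set()).add(go_id)
    return mapping


def read_hierarchy(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (child term, parent term) -> child -> parents."""
    hierarchy: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns (child, parent)")
        hierarchy.setdefault(fields[0], set()).add(fields[1])
    return hierarchy


def read_fluctuation_counts(path: str | Path) -> pd.DataFrame:
    """Fluctuation TSV: strain_id, culture_id, count, n_final."""
    df = read_tsv(path)
    required = {"strain_id", "culture_id", "count", "n_final"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_config(path: str | Path) -> dict:
    """Pipeline configuration from YAML (mapping at top level)."""
    with Path(path).open(encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return config
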