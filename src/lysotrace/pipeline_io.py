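"""Format readers/writers, run configuration, and the packaged fixtures.

Formats handled (all plain text):

* coverage — bedGraph (0-based half-open, converted to 1-based per-base
  depth on read, gaps filled with 0) or two-column TSV (position, depth);
* prophage annotations — GFF3 (feature type ``prophage`` with ``name``,
  ``pac``, ``mode``, ``copy_number`` attributes) or a TSV dialect
  (name, replicon, start, end, mode, pac, copy_number);
* expression tables — TSV with per-replicate ``fpkm_*`` columns (or
  ``log2p5fpkm_*`` columns, transformed back on read);
* qPCR measurements and cell counts — CSV;
* run reports — schema-versioned JSON plus flat TSV.

Two in-package fixtures ship with the code: the LF82 prophage annotation
table (four integrated prophages plus the Cyrano episome) and the LB-growth
expression table encoding the published per-gene folds (with synthetic
silent-gene fillers; see the file headers).
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .induction_stats import CellCounts
from .moron_caller import ExpressionRecord, inverse_log2p5, log2p5
from .prophage_model import ProphageAnnotation, RepliconMap
from .qpcr_quant import QpcrMeasurement
from .virome_coverage import CoverageTrack

__all__ = [
    "RunConfig",
    "read_coverage",
    "write_coverage",
    "read_annotations",
    "read_expression",
    "write_expression",
    "read_qpcr",
    "read_counts",
    "run_report",
    "load_lf82_prophages",
    "load_lf82_expression",
]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """All tunable analysis constants, serialisable to/from YAML."""

    window: int = 5000
    alpha: float = 0.05
    packaging_fraction: float = 1.038
    moron_threshold: float = 5.0
    tmp_ratio: float = 0.15
    instability_factors: dict[str, float] = field(default_factory=dict)
    extent_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window", "alpha", "packaging_fraction", "moron_threshold",
                     "tmp_ratio", "extent_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be > 0")
        for target, factor in self.instability_factors.items():
            if factor <= 0:
                raise ValidationError(
                    f"config: instability factor for {target} must be > 0"
                )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------- coverage


def read_coverage(
    path: str | Path,
    format: str = "bedgraph",
    replicon_id: str | None = None,
    length: int | None = None,
) -> CoverageTrack:
    """Read a per-base coverage track.

    bedGraph intervals are 0-based half-open and must not overlap; gaps are
    filled with zero depth. The TSV dialect is two columns (1-based
    position, depth), one row per base. ``length`` pads/validates the track
    length when the file does not reach the replicon end.
    """
    path = Path(path)
    if format == "bedgraph":
        intervals: list[tuple[str, int, int, float]] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValidationError(f"{path}:{lineno}: need 4 columns")
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if value < 0:
                    raise ValidationError(f"{path}:{lineno}: negative depth")
                if end <= start:
                    raise ValidationError(f"{path}:{lineno}: empty interval")
                intervals.append((chrom, start, end, value))
        if not intervals:
            raise ValidationError(f"{path}: no coverage records")
        chroms = {iv[0] for iv in intervals}
        if replicon_id is None:
            if len(chroms) > 1:
                raise ValidationError(
                    f"{path}: multiple replicons {sorted(chroms)}; pass replicon_id"
                )
            replicon_id = next(iter(chroms))
        intervals = [iv for iv in intervals if iv[0] == replicon_id]
        intervals.sort(key=lambda iv: iv[1])
        for (_, _, e1, _), (_, s2, _, _) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValidationError(f"{path}: overlapping bedGraph intervals")
        n = length if length is not None else intervals[-1][2]
        depth = np.zeros(n, dtype=float)
        for _, s, e, v in intervals:
            if e > n:
                raise ValidationError(f"{path}: interval past declared length {n}")
            depth[s:e] = v  # 0-based half-open maps directly onto the array
        return CoverageTrack(replicon_id=replicon_id, depth=depth)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["position", "depth"])
        if (df["depth"] < 0).any():
            raise ValidationError(f"{path}: negative depth")
        n = length if length is not None else int(df["position"].max())
        depth = np.zeros(n, dtype=float)
        depth[df["position"].to_numpy(dtype=int) - 1] = df["depth"].to_numpy(dtype=float)
        return CoverageTrack(replicon_id=replicon_id or path.stem, depth=depth)
    raise ValidationError(f"unknown coverage format {format!r}")


def write_coverage(track: CoverageTrack, path: str | Path, format: str = "bedgraph") -> None:
    """Write a track as run-length-encoded bedGraph or per-base TSV."""
    path = Path(path)
    if format == "bedgraph":
        with path.open("w") as fh:
            d = track.depth
            starts = np.flatnonzero(np.diff(d, prepend=np.nan) != 0)
            bounds = np.append(starts, d.size)
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{track.replicon_id}\t{a}\t{b}\t{d[a]:g}\n")
    elif format == "tsv":
        with path.open("w") as fh:
            for i, v in enumerate(track.depth, 1):
                fh.write(f"{i}\t{v:g}\n")
    else:
        raise ValidationError(f"unknown coverage format {format!r}")


# ------------------------------------------------------------- annotations


def _parse_opt_int(token: str) -> int | None:
    return None if token in (".", "", "NA") else int(token.replace(",", ""))


def read_annotations(
    path: str | Path, format: str = "tsv", replicon_lengths: dict[str, int] | None = None
) -> list[RepliconMap]:
    """Read prophage annotations into one RepliconMap per replicon."""
    path = Path(path)
    annotations: list[ProphageAnnotation] = []
    if format == "tsv":
        with path.open() as fh:
            header: list[str] | None = None
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if header is None:
                    header = [c.strip().lower() for c in parts]
                    required = {"name", "replicon", "start", "end"}
                    if not required <= set(header):
                        raise ValidationError(
                            f"{path}:{lineno}: header must contain {sorted(required)}"
                        )
                    continue
                rec = dict(zip(header, parts))
                try:
                    annotations.append(
                        ProphageAnnotation(
                            name=rec["name"],
                            replicon_id=rec["replicon"],
                            start=int(rec["start"].replace(",", "")),
                            end=int(rec["end"].replace(",", "")),
                            mode=rec.get("mode", "integrated") or "integrated",
                            pac_position=_parse_opt_int(rec.get("pac", ".")),
                            copy_number=float(rec.get("copy_number", 1) or 1),
                        )
                    )
                except (KeyError, ValueError, ValidationError) as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    elif format == "gff3":
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValidationError(f"{path}:{lineno}: need 9 GFF3 columns")
                if parts[2] != "prophage":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                try:
                    annotations.append(
                        ProphageAnnotation(
                            name=attrs.get("name", attrs.get("ID", f"prophage_{lineno}")),
                            replicon_id=parts[0],
                            start=int(parts[3]),
                            end=int(parts[4]),
                            mode=attrs.get("mode", "integrated"),
                            pac_position=_parse_opt_int(attrs.get("pac", ".")),
                            copy_number=float(attrs.get("copy_number", 1)),
                        )
                    )
                except (ValueError, ValidationError) as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise ValidationError(f"unknown annotation format {format!r}")

    by_replicon: dict[str, list[ProphageAnnotation]] = {}
    for a in annotations:
        by_replicon.setdefault(a.replicon_id, []).append(a)
    maps = []
    for rid, plist in by_replicon.items():
        length = (replicon_lengths or {}).get(rid, max(p.end for p in plist))
        maps.append(RepliconMap(replicon_id=rid, length=length, prophages=plist))
    return maps


# -------------------------------------------------------------- expression


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read a prophage expression TSV.

    Columns: ``gene``, ``prophage``, ``category``, ``operon`` plus any
    number of per-replicate expression columns named ``fpkm_*`` (linear) or
    ``log2p5fpkm_*`` (log2(fpkm+5) storage scale, inverted on read).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm")]
    log_cols = [c for c in df.columns if c.startswith("log2p5fpkm")]
    if not fpkm_cols and not log_cols:
        raise ValidationError(f"{path}: no fpkm_* or log2p5fpkm_* columns")
    records = []
    for _, row in df.iterrows():
        if fpkm_cols:
            values = [float(row[c]) for c in fpkm_cols]
        else:
            values = [inverse_log2p5(float(row[c])) for c in log_cols]
        operon = row.get("operon")
        if pd.isna(operon) or operon in (".", ""):
            operon = None
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene"]),
                prophage=str(row["prophage"]),
                category=str(row.get("category", "candidate")),
                operon_id=operon,
                fpkm_per_replicate=values,
                annotation=str(row.get("annotation", "") or ""),
            )
        )
    return records


def write_expression(
    records: list[ExpressionRecord], path: str | Path, scale: str = "fpkm"
) -> None:
    """Write records as TSV, on the linear or log2(fpkm+5) storage scale."""
    if scale not in ("fpkm", "log2p5fpkm"):
        raise ValidationError(f"unknown scale {scale!r}")
    n_rep = max((len(r.fpkm_per_replicate) for r in records), default=0)
    cols = [f"{scale}_r{i + 1}" for i in range(n_rep)]
    with Path(path).open("w") as fh:
        fh.write("\t".join(["gene", "prophage", "category", "operon", "annotation"] + cols) + "\n")
        for r in records:
            values = [
                f"{(v if scale == 'fpkm' else log2p5(v)):.6g}"
                for v in r.fpkm_per_replicate
            ]
            values += [""] * (n_rep - len(values))
            fh.write(
                "\t".join(
                    [r.gene_id, r.prophage, r.category, r.operon_id or ".",
                     r.annotation] + values
                )
                + "\n"
            )


# -------------------------------------------------------------- CSV inputs


def read_qpcr(path: str | Path) -> list[QpcrMeasurement]:
    """CSV columns: sample_id, target, cq, dilution, replicate[, context]."""
    out = []
    with Path(path).open() as fh:
        for lineno, row in enumerate(csv.DictReader(fh), 2):
            try:
                out.append(
                    QpcrMeasurement(
                        sample_id=row["sample_id"],
                        target=row["target"],
                        cq=float(row["cq"]),
                        dilution_factor=float(row.get("dilution", 1) or 1),
                        replicate=int(row.get("replicate", 1) or 1),
                        context=row.get("context", "in_vitro") or "in_vitro",
                    )
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_counts(path: str | Path) -> list[CellCounts]:
    """CSV columns: n_induced, n_total[, context]."""
    out = []
    with Path(path).open() as fh:
        for lineno, row in enumerate(csv.DictReader(fh), 2):
            try:
                out.append(
                    CellCounts(
                        n_induced=int(row["n_induced"]),
                        n_total=int(row["n_total"]),
                        context=row.get("context", "") or "",
                    )
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


# ------------------------------------------------------------------ report


def run_report(
    results: dict,
    json_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Assemble a machine-readable summary of one analysis run.

    ``results`` maps section names (activity, transduction, quantification,
    morons, ...) to lists of per-feature dicts. The JSON document is
    schema-versioned and records the config checksum and seed so a run can
    be reproduced; the TSV flattens all sections into one table.
    """
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_checksum": config.checksum() if config else None,
        "seed": config.seed if config else None,
        "sections": results,
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=2, default=str))
    if tsv_path is not None:
        rows = []
        for section, entries in results.items():
            for entry in entries:
                rows.append({"section": section, **entry})
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return report


# ---------------------------------------------------------------- fixtures


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("lysotrace").joinpath("data", name)))


def load_lf82_prophages() -> list[RepliconMap]:
    """The packaged LF82 prophage annotation table (4 integrated + 1 episome)."""
    return read_annotations(_fixture_path("lf82_prophages.tsv"), format="tsv")


def load_lf82_expression() -> list[ExpressionRecord]:
    """The packaged LB-growth expression fixture for moron calling.

    Encodes the published per-gene folds over each prophage's local median
    background; the silent bulk of each prophage is represented by synthetic
    filler genes (see the file header).
    """
    return read_expression(_fixture_path("lf82_lb_expression.tsv"))
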