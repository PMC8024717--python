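"""Readers and writers for MAF-like mutation tables, SEG-like segment tables,
assembly fixtures, and run configuration files.

All tables are plain tab-delimited text with a header line; column order is
irrelevant and line endings may be Unix or DOS.  Rows that violate the domain
invariants are rejected with row-addressed messages.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .model import (
    AssemblySpec,
    MutationRecord,
    RunConfig,
    Segment,
    SegmentProfile,
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


MUTATION_COLUMNS = [
    "sample_id", "component_id", "chrom", "pos", "ref", "alt",
    "variant_class", "gene", "effect", "t_ref", "t_alt", "n_ref", "n_alt",
    "hotspot_flag",
]

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]

_BOOL_TRUE = {"true", "1", "yes", "t"}
_BOOL_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise FormatError(f"row {row}: column {column!r}: cannot parse boolean {value!r}")


def _parse_int(value, row: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row}: column {column!r}: non-numeric value {value!r}") from None


def read_mutations(path: str | Path, dialect: str = "maf_like") -> list[MutationRecord]:
    """Read a MAF-like tab-delimited mutation table into MutationRecord objects.

    Row numbers in error messages are 1-based over data rows (header excluded).
    """
    if dialect != "maf_like":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            rec = MutationRecord(
                sample_id=row["sample_id"],
                component_id=row["component_id"],
                chrom=row["chrom"],
                pos=_parse_int(row["pos"], i, "pos"),
                ref=row["ref"],
                alt=row["alt"],
                variant_class=row["variant_class"],
                gene=row["gene"],
                effect=row["effect"] or "other",
                t_ref=_parse_int(row["t_ref"], i, "t_ref"),
                t_alt=_parse_int(row["t_alt"], i, "t_alt"),
                n_ref=_parse_int(row["n_ref"], i, "n_ref"),
                n_alt=_parse_int(row["n_alt"], i, "n_alt"),
                hotspot_flag=_parse_bool(row["hotspot_flag"], i, "hotspot_flag"),
            )
        except FormatError:
            raise
        except ValueError as e:
            raise FormatError(f"row {i}: {e}") from None
        records.append(rec)
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {c: getattr(r, c) for c in MUTATION_COLUMNS}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> SegmentProfile:
    """Read a SEG-like table into a canonicalized SegmentProfile.

    Purity, ploidy and the sample id travel in ``#key=value`` header comments::

        #sample_id=S1
        #purity=0.8
        #ploidy=2.0
        chrom	start	end	total_cn	minor_cn
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    for key in ("sample_id", "purity", "ploidy"):
        if key not in meta:
            raise FormatError(f"{path}: missing #{key}= header comment")
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep="\t", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            segments.append(
                Segment(
                    chrom=row["chrom"],
                    start=_parse_int(row["start"], i, "start"),
                    end=_parse_int(row["end"], i, "end"),
                    total_cn=_parse_int(row["total_cn"], i, "total_cn"),
                    minor_cn=_parse_int(row["minor_cn"], i, "minor_cn"),
                )
            )
        except FormatError:
            raise
        except ValueError as e:
            raise FormatError(f"row {i}: {e}") from None
    profile = SegmentProfile(
        sample_id=meta["sample_id"],
        segments=segments,
        purity=float(meta["purity"]),
        ploidy=float(meta["ploidy"]),
    )
    return profile.canonicalize()


def write_segments(profile: SegmentProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#purity={profile.purity}\n")
        fh.write(f"#ploidy={profile.ploidy}\n")
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in profile.segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn}\t{s.minor_cn}\n")


def _toy_assembly() -> AssemblySpec:
    # 3 chromosomes of 100 Mb, centromeres at 45-55 Mb -> 6 arms of 45 Mb
    chroms = [(str(i), 100_000_000) for i in (1, 2, 3)]
    cens = {str(i): (45_000_000, 55_000_000) for i in (1, 2, 3)}
    return AssemblySpec(chroms, cens)


def read_assembly_table(path: str | Path) -> AssemblySpec:
    """Read an assembly TSV with columns chrom, length, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["chrom", "length", "cen_start", "cen_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    chroms: list[tuple[str, int]] = []
    cens: dict[str, tuple[int, int]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        name = row["chrom"]
        chroms.append((name, _parse_int(row["length"], i, "length")))
        if str(row["cen_start"]).strip() in ("", "nan") or str(row["cen_end"]).strip() in ("", "nan"):
            raise FormatError(f"row {i}: chromosome {name} is missing a centromere interval")
        cens[name] = (
            _parse_int(row["cen_start"], i, "cen_start"),
            _parse_int(row["cen_end"], i, "cen_end"),
        )
    return AssemblySpec(chroms, cens)


def load_assembly(name_or_path: str | Path) -> AssemblySpec:
    """Load a built-in assembly ('toy', 'hg19_fixture') or an assembly TSV."""
    if name_or_path == "toy":
        return _toy_assembly()
    if name_or_path == "hg19_fixture":
        ref = importlib.resources.files("biphasic.data").joinpath("hg19_assembly.tsv")
        with importlib.resources.as_file(ref) as p:
            return read_assembly_table(p)
    return read_assembly_table(name_or_path)


def read_config(path: str | Path) -> RunConfig:
    """Read a YAML run-configuration file; omitted keys take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(config, k) for k in RunConfig.__dataclass_fields__}, fh)
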