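"""Readers and writers for the package's file formats.

Formats: constraint specs and designs as JSON; count / CPM / enrichment
tables as 2-column TSV with a header line; sub-pools as IUPAC FASTA; beam
parameters as JSON with the canonical key names. write/read round-trips are
identity for all of them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from .design import LibraryDesign, MotifConstraintSpec, PairConstraint, SubPool
from .ml import BeamSearchParams
from .selection import CountTable


class FormatError(ValueError):
    pass


# -- constraint specs -------------------------------------------------------


def spec_to_json(spec: MotifConstraintSpec) -> dict:
    return {
        "length": spec.length,
        "conserved": {str(p): b for p, b in sorted(spec.conserved.items())},
        "variable_unpaired": {
            str(p): "".join(sorted(bs)) for p, bs in sorted(spec.variable_unpaired.items())
        },
        "pairs": [
            {
                "pos5": pc.pos5,
                "pos3": pc.pos3,
                "allowed_pairs": sorted(pc.allowed_pairs),
            }
            for pc in spec.pairs
        ],
    }


def spec_from_json(obj: Mapping) -> MotifConstraintSpec:
    try:
        return MotifConstraintSpec(
            length=int(obj["length"]),
            conserved={int(p): b for p, b in obj.get("conserved", {}).items()},
            variable_unpaired={
                int(p): frozenset(bs) for p, bs in obj.get("variable_unpaired", {}).items()
            },
            pairs=[
                PairConstraint(
                    pos5=int(d["pos5"]),
                    pos3=int(d["pos3"]),
                    allowed_pairs=frozenset(d["allowed_pairs"]),
                )
                for d in obj.get("pairs", [])
            ],
        )
    except KeyError as exc:
        raise FormatError(f"spec JSON missing key: {exc}") from None


def load_spec(path) -> MotifConstraintSpec:
    return spec_from_json(json.loads(Path(path).read_text()))


def save_spec(path, spec: MotifConstraintSpec) -> None:
    Path(path).write_text(json.dumps(spec_to_json(spec), indent=1) + "\n")


# -- designs ----------------------------------------------------------------


def design_to_json(design: LibraryDesign) -> dict:
    out = {
        "subpools": [sp.degenerate_sequence for sp in design.subpools],
        "weights": [sp.weight for sp in design.subpools],
    }
    if design.position_groups is not None:
        out["position_groups"] = [list(g) for g in design.position_groups]
    return out


def design_from_json(obj: Mapping) -> LibraryDesign:
    pools = obj.get("subpools")
    if not pools:
        raise FormatError("design JSON has no subpools")
    weights = obj.get("weights") or [1.0 / len(pools)] * len(pools)
    groups = obj.get("position_groups")
    return LibraryDesign(
        subpools=[SubPool(s, float(w)) for s, w in zip(pools, weights)],
        position_groups=tuple(tuple(g) for g in groups) if groups else None,
    )


def load_design(path) -> LibraryDesign:
    return design_from_json(json.loads(Path(path).read_text()))


def save_design(path, design: LibraryDesign) -> None:
    Path(path).write_text(json.dumps(design_to_json(design), indent=1) + "\n")


def design_to_fasta(path, design: LibraryDesign, name: str = "subpool") -> None:
    """Write sub-pools as IUPAC FASTA; weights recorded in the description."""
    with open(path, "w") as fh:
        for k, sp in enumerate(design.subpools, start=1):
            fh.write(f">{name}_{k} weight={sp.weight:.12g}\n{sp.degenerate_sequence}\n")


def design_from_fasta(path) -> LibraryDesign:
    pools: list[SubPool] = []
    seqs: list[tuple[str, float]] = []
    header = None
    weight = None
    chunks: list[str] = []

    def flush():
        if header is not None:
            seqs.append(("".join(chunks), weight))

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header, weight, chunks = line, None, []
            for tok in line[1:].split():
                if tok.startswith("weight="):
                    weight = float(tok.split("=", 1)[1])
        else:
            if header is None:
                raise FormatError(f"line {lineno}: sequence before FASTA header")
            chunks.append(line.upper())
    flush()
    if not seqs:
        raise FormatError("empty FASTA")
    default_w = 1.0 / len(seqs)
    for s, w in seqs:
        pools.append(SubPool(s, w if w is not None else default_w))
    return LibraryDesign(pools)


# -- count and value tables -------------------------------------------------


def save_count_table(path, table: CountTable) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for s in sorted(table.counts):
            fh.write(f"{s}\t{table.counts[s]}\n")


def load_count_table(path) -> CountTable:
    counts: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["sequence", "count"]:
        raise FormatError(f"{path}: expected header 'sequence\\tcount'")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path} line {lineno}: expected 2 tab-separated fields")
        seq, raw = fields
        try:
            count = int(raw)
        except ValueError:
            raise FormatError(f"{path} line {lineno}: non-integer count {raw!r}") from None
        if count <= 0:
            raise FormatError(f"{path} line {lineno}: count must be positive")
        if seq in counts:
            raise FormatError(f"{path} line {lineno}: duplicate sequence {seq}")
        counts[seq] = count
    if not counts:
        raise FormatError(f"{path}: no data rows")
    return CountTable(counts)


def save_value_table(path, values: Mapping[str, float], column: str = "value") -> None:
    """Write a sequence -> float table (CPM, enrichment, ...) as TSV."""
    with open(path, "w") as fh:
        fh.write(f"sequence\t{column}\n")
        for s in sorted(values):
            fh.write(f"{s}\t{values[s]:.10g}\n")


def load_value_table(path) -> dict[str, float]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("sequence\t"):
        raise FormatError(f"{path}: expected a 'sequence<TAB>...' header")
    out: dict[str, float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path} line {lineno}: expected 2 tab-separated fields")
        out[fields[0]] = float(fields[1])
    return out


# -- beam parameters and reports -------------------------------------------


def load_beam_params(path) -> BeamSearchParams:
    return BeamSearchParams.from_json(json.loads(Path(path).read_text()))


def save_beam_params(path, params: BeamSearchParams) -> None:
    Path(path).write_text(json.dumps(params.to_json(), indent=1) + "\n")


def write_report(path, payload: dict, config: Mapping | None = None) -> None:
    """Write a JSON report with an embedded provenance record."""
    from . import __version__

    record = dict(payload)
    record["_provenance"] = {
        "package": "motifspace",
        "version": __version__,
        "config": dict(config or {}),
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")
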