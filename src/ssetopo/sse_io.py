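"""Readers and writers for every external representation of the pipeline.

Three families of files are handled:

* atomic models with secondary-structure annotation — PDB or mmCIF parsed
  with gemmi; HELIX/SHEET (struct_conf/struct_sheet_range) records supply the
  annotation, optionally overridden by a sidecar TSV with columns
  ``chain  start_res  end_res  type`` (type H or S);
* density-stick files — the axis-point output of map-side SSE detectors,
  as JSON (list of objects with ``stick_id``, ``sse_type``, optional
  ``confidence`` and ``points``) or an equivalent TSV dialect with one point
  per row;
* ground-truth and topology tables — TSV with columns
  ``sse_id  stick_id  direction  score`` where ``-`` marks an absent value;
  unmatched model SSEs appear as rows with stick_id ``-`` and unmatched
  sticks as rows with sse_id ``-``.

Model SSE identifiers are assigned deterministically as H1..Hk / S1..Sl in
sequence order (sorted by chain, then start residue), which makes them
reproducible class labels for the correspondence classifier.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import geometry
from .errors import InputError

logger = logging.getLogger(__name__)

SSE_TYPES = ("helix", "strand")

__all__ = [
    "ModelSSE",
    "DensityStick",
    "GroundTruth",
    "read_model_sses",
    "read_sticks",
    "write_sticks",
    "read_ground_truth",
    "write_ground_truth",
    "write_topology",
    "read_topology",
    "natural_id_key",
]


def natural_id_key(sse_id: str):
    """Sort key putting H2 before H10 (letter prefix, then numeric suffix)."""
    m = re.fullmatch(r"([A-Za-z]+)(\d+)", sse_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (sse_id, 0)


@dataclass
class ModelSSE:
    """One model-derived SSE: an ordered N→C Cα trace plus metadata.

    ``axis_vector`` is derived on construction (first principal direction,
    oriented first→last point).
    """

    sse_id: str
    sse_type: str
    chain_id: str
    residue_range: tuple
    calpha_coords: np.ndarray
    axis_vector: np.ndarray = field(init=False)
    residue_count: int = field(init=False)

    def __post_init__(self) -> None:
        if self.sse_type not in SSE_TYPES:
            raise InputError(f"unknown SSE type {self.sse_type!r}")
        self.calpha_coords = np.asarray(self.calpha_coords, dtype=float)
        if self.calpha_coords.ndim != 2 or self.calpha_coords.shape[1] != 3:
            raise InputError("calpha_coords must be an (n, 3) array")
        if len(self.calpha_coords) < 2:
            raise InputError(
                f"SSE {self.sse_id}: needs at least 2 Cα points, "
                f"got {len(self.calpha_coords)}"
            )
        if not np.isfinite(self.calpha_coords).all():
            raise InputError(f"SSE {self.sse_id}: non-finite coordinates")
        self.residue_count = len(self.calpha_coords)
        self.axis_vector = geometry.compute_axis(self.calpha_coords)


@dataclass
class DensityStick:
    """One map-derived SSE: ordered axis points of a detected density stick."""

    stick_id: str
    sse_type: str
    axis_points: np.ndarray
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.sse_type not in SSE_TYPES:
            raise InputError(f"unknown SSE type {self.sse_type!r}")
        self.axis_points = np.asarray(self.axis_points, dtype=float)
        if self.axis_points.ndim == 1 and self.axis_points.size == 3:
            self.axis_points = self.axis_points[None, :]
        if self.axis_points.ndim != 2 or self.axis_points.shape[1] != 3:
            raise InputError("axis_points must be an (n, 3) array")
        if len(self.axis_points) < 1:
            raise InputError(f"stick {self.stick_id}: empty point list")
        if not np.isfinite(self.axis_points).all():
            raise InputError(f"stick {self.stick_id}: non-finite coordinates")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise InputError(
                f"stick {self.stick_id}: confidence must be in [0, 1]"
            )


@dataclass
class GroundTruth:
    """Reference correspondence: matched (sse, stick, direction) triples plus
    the model SSEs and sticks that genuinely have no counterpart."""

    pairs: list  # of (sse_id, stick_id, direction)
    unmatched_sses: list = field(default_factory=list)
    unmatched_sticks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sse_seen: set = set()
        stick_seen: set = set()
        for sse_id, stick_id, direction in self.pairs:
            if direction not in (+1, -1):
                raise InputError(
                    f"ground-truth direction must be +1 or -1, got {direction}"
                )
            if sse_id in sse_seen or stick_id in stick_seen:
                raise InputError("ground truth is not one-to-one")
            sse_seen.add(sse_id)
            stick_seen.add(stick_id)
        for sid in self.unmatched_sses:
            if sid in sse_seen:
                raise InputError(f"SSE {sid} both matched and unmatched")
            sse_seen.add(sid)
        for vid in self.unmatched_sticks:
            if vid in stick_seen:
                raise InputError(f"stick {vid} both matched and unmatched")
            stick_seen.add(vid)

    @property
    def sse_ids(self) -> set:
        return {p[0] for p in self.pairs} | set(self.unmatched_sses)

    @property
    def stick_ids(self) -> set:
        return {p[1] for p in self.pairs} | set(self.unmatched_sticks)


# ---------------------------------------------------------------------------
# atomic models

_TYPE_TOKENS = {"H": "helix", "HELIX": "helix", "S": "strand", "SHEET": "strand",
                "STRAND": "strand"}


def _read_annotation_table(path) -> list:
    """Sidecar TSV: chain, start_res, end_res, type(H|S)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chain", "start_res", "end_res", "type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"annotation table {path} must have columns {sorted(required)}"
            )
        for row in reader:
            token = row["type"].strip().upper()
            if token not in _TYPE_TOKENS:
                raise InputError(f"unknown SSE type token {row['type']!r} in {path}")
            rows.append(
                (
                    row["chain"].strip(),
                    int(row["start_res"]),
                    int(row["end_res"]),
                    _TYPE_TOKENS[token],
                )
            )
    return rows


def _records_from_structure(st: gemmi.Structure) -> list:
    anns = []
    for hel in st.helices:
        anns.append(
            (
                hel.start.chain_name,
                hel.start.res_id.seqid.num,
                hel.end.res_id.seqid.num,
                "helix",
            )
        )
    for sheet in st.sheets:
        for strand in sheet.strands:
            anns.append(
                (
                    strand.start.chain_name,
                    strand.start.res_id.seqid.num,
                    strand.end.res_id.seqid.num,
                    "strand",
                )
            )
    return anns


def read_model_sses(
    model_path,
    annotation=None,
    min_residues: int = 3,
) -> list:
    """Extract one ordered Cα trace per annotated helix/strand.

    Annotation comes from the model's own HELIX/SHEET (or mmCIF equivalent)
    records; a sidecar table, when given, overrides them (predicted models
    often ship without records).  SSEs shorter than ``min_residues`` are
    dropped with a warning.  IDs are assigned H1..Hk / S1..Sl in sequence
    order (chain, then start residue), independent of record order.
    """
    model_path = Path(model_path)
    try:
        st = gemmi.read_structure(str(model_path))
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise InputError(f"cannot parse model file {model_path}: {exc}") from exc

    if annotation is not None:
        anns = _read_annotation_table(annotation)
    else:
        anns = _records_from_structure(st)
    if not anns:
        raise InputError(
            f"{model_path}: no SSE annotation (HELIX/SHEET records or sidecar table)"
        )
    if len(st) == 0:
        raise InputError(f"{model_path}: structure contains no models")
    model = st[0]

    # index Cα positions per chain by residue number
    ca_by_chain: dict = {}
    for chain in model:
        per = ca_by_chain.setdefault(chain.name, {})
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is not None:
                per[res.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])

    anns_sorted = sorted(anns, key=lambda a: (a[0], a[1], a[2]))
    kept = []
    for chain_id, start, end, sse_type in anns_sorted:
        if chain_id not in ca_by_chain:
            raise InputError(
                f"annotation/model mismatch: chain {chain_id!r} not in {model_path}"
            )
        per = ca_by_chain[chain_id]
        coords = []
        for num in range(start, end + 1):
            if num not in per:
                raise InputError(
                    f"annotation/model mismatch: residue {chain_id}/{num} "
                    f"has no Cα in {model_path}"
                )
            coords.append(per[num])
        if len(coords) < min_residues:
            logger.warning(
                "dropping %s %s/%d-%d: %d residue(s) < minimum %d",
                sse_type, chain_id, start, end, len(coords), min_residues,
            )
            continue
        kept.append((chain_id, start, end, sse_type, np.array(coords)))

    if not kept:
        raise InputError(f"{model_path}: zero SSEs remain after length filtering")

    sses = []
    counters = {"helix": 0, "strand": 0}
    prefix = {"helix": "H", "strand": "S"}
    for chain_id, start, end, sse_type, coords in kept:
        counters[sse_type] += 1
        sses.append(
            ModelSSE(
                sse_id=f"{prefix[sse_type]}{counters[sse_type]}",
                sse_type=sse_type,
                chain_id=chain_id,
                residue_range=(start, end),
                calpha_coords=coords,
            )
        )
    return sses


def write_model_sses(sses: list, model_path, annotation_path=None) -> None:
    """Write model SSEs as a Cα-only PDB (or mmCIF) with HELIX/SHEET records.

    Optionally also writes the sidecar annotation TSV.  Residues are ALA
    placeholders — only the Cα geometry and the SSE annotation matter here.
    """
    model_path = Path(model_path)
    st = gemmi.Structure()
    st.name = "ssetopo synthetic model"
    model = gemmi.Model("1")
    chains: dict = {}
    for sse in sorted(sses, key=lambda s: (s.chain_id, s.residue_range[0])):
        chain = chains.get(sse.chain_id)
        if chain is None:
            chain = gemmi.Chain(sse.chain_id)
            chains[sse.chain_id] = chain
        start = sse.residue_range[0]
        for offset, (x, y, z) in enumerate(sse.calpha_coords):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(start + offset, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
            chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    for sse in sses:
        start, end = sse.residue_range
        if sse.sse_type == "helix":
            hel = gemmi.Helix()
            hel.start = gemmi.AtomAddress(sse.chain_id, gemmi.SeqId(start, " "),
                                          "ALA", "")
            hel.end = gemmi.AtomAddress(sse.chain_id, gemmi.SeqId(end, " "),
                                        "ALA", "")
            st.helices.append(hel)
        else:
            sheet = gemmi.Sheet(sse.sse_id)
            strand = gemmi.Sheet.Strand()
            strand.start = gemmi.AtomAddress(sse.chain_id, gemmi.SeqId(start, " "),
                                             "ALA", "")
            strand.end = gemmi.AtomAddress(sse.chain_id, gemmi.SeqId(end, " "),
                                           "ALA", "")
            sheet.strands.append(strand)
            st.sheets.append(sheet)
    st.setup_entities()
    if model_path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(model_path))
    else:
        st.write_pdb(str(model_path))
    if annotation_path is not None:
        with open(annotation_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["chain", "start_res", "end_res", "type"])
            for sse in sorted(sses, key=lambda s: (s.chain_id, s.residue_range[0])):
                writer.writerow(
                    [
                        sse.chain_id,
                        sse.residue_range[0],
                        sse.residue_range[1],
                        "H" if sse.sse_type == "helix" else "S",
                    ]
                )


# ---------------------------------------------------------------------------
# density sticks

def read_sticks(stick_path) -> list:
    """Read a stick file (JSON or TSV, chosen by extension)."""
    stick_path = Path(stick_path)
    if stick_path.suffix.lower() == ".json":
        return _read_sticks_json(stick_path)
    return _read_sticks_tsv(stick_path)


def _validate_stick_list(sticks: list) -> list:
    seen = set()
    for s in sticks:
        if s.stick_id in seen:
            raise InputError(f"duplicate stick_id {s.stick_id!r}")
        seen.add(s.stick_id)
    return sticks


def _read_sticks_json(path: Path) -> list:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise InputError(f"cannot parse stick file {path}: {exc}") from exc
    if not isinstance(data, list):
        raise InputError(f"{path}: stick JSON must be a list of objects")
    sticks = []
    for entry in data:
        sticks.append(
            DensityStick(
                stick_id=str(entry["stick_id"]),
                sse_type=str(entry["sse_type"]),
                axis_points=np.asarray(entry["points"], dtype=float),
                confidence=entry.get("confidence"),
            )
        )
    return _validate_stick_list(sticks)


def _read_sticks_tsv(path: Path) -> list:
    groups: dict = {}
    order: list = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"stick_id", "sse_type", "x", "y", "z"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(f"{path}: stick TSV needs columns {sorted(required)}")
        for row in reader:
            sid = row["stick_id"]
            if sid not in groups:
                conf = row.get("confidence")
                conf = None if conf in (None, "", "-") else float(conf)
                groups[sid] = {"sse_type": row["sse_type"], "confidence": conf,
                               "points": []}
                order.append(sid)
            groups[sid]["points"].append(
                (float(row["x"]), float(row["y"]), float(row["z"]))
            )
    sticks = [
        DensityStick(
            stick_id=sid,
            sse_type=groups[sid]["sse_type"],
            axis_points=np.asarray(groups[sid]["points"]),
            confidence=groups[sid]["confidence"],
        )
        for sid in order
    ]
    return _validate_stick_list(sticks)


def write_sticks(sticks: list, out_path) -> None:
    """Write sticks as JSON or TSV (chosen by extension); round-trips exactly
    (coordinates are serialized at full precision)."""
    out_path = Path(out_path)
    _validate_stick_list(sticks)
    if out_path.suffix.lower() == ".json":
        data = [
            {
                "stick_id": s.stick_id,
                "sse_type": s.sse_type,
                "confidence": s.confidence,
                "points": s.axis_points.tolist(),
            }
            for s in sticks
        ]
        out_path.write_text(json.dumps(data, indent=1) + "\n")
        return
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["stick_id", "sse_type", "confidence", "x", "y", "z"])
        for s in sticks:
            conf = "-" if s.confidence is None else repr(float(s.confidence))
            for x, y, z in s.axis_points:
                writer.writerow([s.stick_id, s.sse_type, conf,
                                 repr(float(x)), repr(float(y)), repr(float(z))])


# ---------------------------------------------------------------------------
# ground truth and topology tables

_HEADER = ["sse_id", "stick_id", "direction", "score"]


def _format_direction(direction) -> str:
    if direction in (0, None):
        return "-"
    return f"{direction:+d}"


def write_topology(matches, out_path) -> None:
    """Serialize a correspondence set as a deterministic, sorted TSV.

    Matched pairs come first (sorted by sse_id), then unmatched model SSEs
    (stick_id ``-``), then unmatched sticks (sse_id ``-``).
    """
    out_path = Path(out_path)
    lines = []
    for pair in sorted(matches.pairs, key=lambda p: natural_id_key(p.sse_id)):
        score = "-" if pair.score is None else repr(float(pair.score))
        lines.append(
            [pair.sse_id, pair.stick_id, _format_direction(pair.direction), score]
        )
    for sid in sorted(matches.unmatched_sses, key=natural_id_key):
        lines.append([sid, "-", "-", "-"])
    for vid in sorted(matches.unmatched_sticks, key=natural_id_key):
        lines.append(["-", vid, "-", "-"])
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        writer.writerows(lines)


def read_topology(path):
    """Read a topology TSV back into a correspondence set."""
    from .correspondence import CorrespondenceSet, MatchRecord

    pairs, un_sses, un_sticks = _read_table(path)
    return CorrespondenceSet(
        pairs=[
            MatchRecord(sse_id=s, stick_id=v, score=score, direction=direction)
            for s, v, direction, score in pairs
        ],
        unmatched_sses=un_sses,
        unmatched_sticks=un_sticks,
    )


def _read_table(path):
    pairs = []
    un_sses = []
    un_sticks = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_HEADER) <= set(reader.fieldnames):
            raise InputError(f"{path}: expected columns {_HEADER}")
        for row in reader:
            sse_id = row["sse_id"].strip()
            stick_id = row["stick_id"].strip()
            if sse_id == "-" and stick_id == "-":
                raise InputError(f"{path}: row with neither sse_id nor stick_id")
            if stick_id == "-":
                un_sses.append(sse_id)
                continue
            if sse_id == "-":
                un_sticks.append(stick_id)
                continue
            direction = row["direction"].strip()
            direction = 0 if direction == "-" else int(direction)
            score = row["score"].strip()
            score = None if score == "-" else float(score)
            pairs.append((sse_id, stick_id, direction, score))
    return pairs, un_sses, un_sticks


def write_ground_truth(truth: GroundTruth, out_path) -> None:
    """Ground truth uses the same table dialect as topology output."""
    out_path = Path(out_path)
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for sse_id, stick_id, direction in sorted(
            truth.pairs, key=lambda p: natural_id_key(p[0])
        ):
            writer.writerow([sse_id, stick_id, _format_direction(direction), "-"])
        for sid in sorted(truth.unmatched_sses, key=natural_id_key):
            writer.writerow([sid, "-", "-", "-"])
        for vid in sorted(truth.unmatched_sticks, key=natural_id_key):
            writer.writerow(["-", vid, "-", "-"])


def read_ground_truth(path) -> GroundTruth:
    pairs, un_sses, un_sticks = _read_table(path)
    gt_pairs = []
    for sse_id, stick_id, direction, _score in pairs:
        if direction == 0:
            raise InputError(
                f"{path}: ground-truth pair {sse_id}/{stick_id} lacks a direction"
            )
        gt_pairs.append((sse_id, stick_id, direction))
    return GroundTruth(
        pairs=gt_pairs, unmatched_sses=un_sses, unmatched_sticks=un_sticks
    )
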