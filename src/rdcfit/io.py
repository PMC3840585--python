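"""Readers and writers: RDC data tables, PDB vector extraction, the
selection mini-language, session state, and ensemble list files.

Data-table dialect (fixed by this package; documented in the README): each
non-comment line has at least 9 whitespace-separated fields,

    x1 y1 z1  x2 y2 z2  d_obs  dmax  error  [comment ...]

coordinates in Angstrom, couplings in Hz, ``dmax`` the per-row maximum
coupling at 1.0 A (the file value overrides the built-in pair table), and
``d_obs = 999`` marking an unobserved row.  Lines starting with '#' and
blank lines are ignored; equations are numbered 1..n in file order.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from .core import (MISSING, PairType, RDCDatum, RDCSet, get_pair_type,
                   make_vector)

__all__ = [
    "read_redcat_file", "write_redcat_file", "pdb_to_rdcset",
    "SelectionExpr", "parse_selection", "render_selection",
    "SessionState", "save_state", "load_state", "read_ensemble_file",
]

logger = logging.getLogger(__name__)

STATE_SCHEMA_VERSION = 1


class DataFileError(ValueError):
    """Malformed RDC data table."""


class SelectionError(ValueError):
    """Malformed or out-of-range selection expression."""


def _parse_line(line: str, lineno: int) -> RDCDatum | None:
    fields = line.split()
    if not fields or fields[0].startswith("#"):
        return None
    if len(fields) < 9:
        raise DataFileError(
            f"line {lineno}: expected >= 9 fields "
            f"(x1 y1 z1 x2 y2 z2 d_obs dmax error [comment]), got {len(fields)}"
        )
    numbers = []
    for col, text in enumerate(fields[:9], start=1):
        try:
            numbers.append(float(text))
        except ValueError:
            raise DataFileError(
                f"line {lineno}, column {col}: non-numeric field {text!r}"
            ) from None
    x1, y1, z1, x2, y2, z2, d_obs, dmax, error = numbers
    label = " ".join(fields[9:])
    missing = d_obs == MISSING
    return RDCDatum(
        vector=make_vector((x1, y1, z1), (x2, y2, z2)),
        d_obs=d_obs, error=error, dmax=dmax, index=0, label=label,
        missing=missing,
    )


def read_redcat_file(path) -> RDCSet:
    """Parse an RDC data table into an :class:`~rdcfit.core.RDCSet`."""
    data = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            datum = _parse_line(line, lineno)
            if datum is not None:
                from dataclasses import replace

                data.append(replace(datum, index=len(data) + 1))
    return RDCSet(data=data, medium_label=os.path.basename(str(path)))


def write_redcat_file(rdcs: RDCSet, path) -> None:
    """Write an RDC data table (numeric values to 6 significant figures)."""
    with open(path, "w") as fh:
        for d in rdcs.data:
            xi, yi, zi = d.vector.coords_i
            xj, yj, zj = d.vector.coords_j
            d_obs = MISSING if d.missing else d.d_obs
            vals = " ".join(f"{v:.6g}" for v in
                            (xi, yi, zi, xj, yj, zj, d_obs, d.dmax, d.error))
            fh.write(f"{vals} {d.label}".rstrip() + "\n")


# ---------------------------------------------------------------------------
# PDB extraction

#: atom names per pair type: (atom_i, atom_j, residue offset of atom_i).
#: offset -1 means atom_i comes from the preceding residue (sequential pair).
_PAIR_ATOMS = {
    "n-h": ("N", "H", 0),
    "c-n": ("C", "N", -1),
    "c-h": ("C", "H", -1),
    "ca-ha": ("CA", "HA", 0),
    "ca-c": ("CA", "C", 0),
    "h-h": ("HA", "H", 0),
}


def pdb_to_rdcset(
    pdb_path,
    pairs,
    residue_range: tuple[int, int] | None = None,
    chain: str | None = None,
    default_error: float = 1.0,
) -> RDCSet:
    """Extract interaction-vector template rows from a PDB structure.

    One row per resolvable pair per residue, with coordinates and the
    built-in dmax filled in and ``d_obs`` left missing (999) so the file can
    be completed with measured couplings.  Sequential pairs (e.g. the
    C(i-1)-N(i) amide bond partners) span residue boundaries.  Only the
    first model is used; alternate locations resolve to the highest
    occupancy (first wins a tie); residues with insertion codes are treated
    as distinct.  Missing atoms are skipped and counted in a log message.
    """
    import gemmi

    structure = gemmi.read_pdb(str(pdb_path))
    if len(structure) == 0:
        raise ValueError(f"{pdb_path}: no models")
    model = structure[0]
    pair_types: list[PairType] = [
        get_pair_type(p) if isinstance(p, str) else p for p in pairs
    ]
    data = []
    n_skipped = 0

    def best_atom(residue, name):
        candidates = [a for a in residue if a.name == name]
        if not candidates:
            return None
        return max(candidates, key=lambda a: a.occ)  # first on tie

    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        residues = list(ch)
        for k, res in enumerate(residues):
            seqid = res.seqid.num
            if residue_range is not None and not (
                residue_range[0] <= seqid <= residue_range[1]
            ):
                continue
            for pt in pair_types:
                name_i, name_j, offset = _PAIR_ATOMS[pt.name.lower()]
                res_i = residues[k + offset] if 0 <= k + offset < len(residues) else None
                if offset and (res_i is None or res_i.seqid.num != seqid + offset):
                    n_skipped += 1
                    continue
                atom_i = best_atom(res_i, name_i) if res_i is not None else None
                atom_j = best_atom(res, name_j)
                if atom_i is None or atom_j is None:
                    n_skipped += 1
                    continue
                pi, pj = atom_i.pos, atom_j.pos
                data.append(RDCDatum(
                    vector=make_vector((pi.x, pi.y, pi.z), (pj.x, pj.y, pj.z)),
                    d_obs=MISSING, error=default_error, dmax=pt.dmax_unit,
                    index=len(data) + 1,
                    label=f"{ch.name}:{seqid}:{res.name}:{pt.name}",
                    missing=True,
                ))
    if n_skipped:
        logger.info("pdb_to_rdcset: skipped %d unresolvable pairs", n_skipped)
    if not data:
        raise ValueError(f"{pdb_path}: no resolvable pairs for {pairs}")
    return RDCSet(data=data, medium_label=os.path.basename(str(pdb_path)))


# ---------------------------------------------------------------------------
# Selection mini-language

@dataclass(frozen=True)
class SelectionExpr:
    """Parsed selection: tokens applied left-to-right to the current mask.

    ``*`` selects all, ``!`` negates, ``~`` deselects rows with missing
    observations, ``a-b`` selects an inclusive 1-based range, a bare integer
    selects one row, and ``,`` separates commands.
    """

    source: str
    tokens: tuple  # of ("STAR",) | ("NEGATE",) | ("PRUNE",) | ("INDEX", k) | ("RANGE", a, b)


def _parse_tokens(expr: str) -> tuple:
    tokens = []
    for raw in expr.split(","):
        cmd = raw.strip()
        if not cmd:
            raise SelectionError(f"empty command in selection {expr!r}")
        if cmd == "*":
            tokens.append(("STAR",))
        elif cmd == "!":
            tokens.append(("NEGATE",))
        elif cmd == "~":
            tokens.append(("PRUNE",))
        elif "-" in cmd[1:]:  # allow leading '-' to fail as malformed below
            a_text, _, b_text = cmd.partition("-")
            try:
                a, b = int(a_text), int(b_text)
            except ValueError:
                raise SelectionError(f"malformed range token {cmd!r}") from None
            if a < 1 or b < a:
                raise SelectionError(f"invalid range {cmd!r}: need 1 <= a <= b")
            tokens.append(("RANGE", a, b))
        else:
            try:
                k = int(cmd)
            except ValueError:
                raise SelectionError(f"malformed token {cmd!r}") from None
            if k < 1:
                raise SelectionError(f"indices are 1-based, got {k}")
            tokens.append(("INDEX", k))
    return tuple(tokens)


def parse_expression(expr: str) -> SelectionExpr:
    return SelectionExpr(source=expr, tokens=_parse_tokens(expr))


def render_selection(sel: SelectionExpr) -> str:
    """Render tokens back to text; parse(render(sel)) has the same tokens."""
    parts = []
    for tok in sel.tokens:
        if tok[0] == "STAR":
            parts.append("*")
        elif tok[0] == "NEGATE":
            parts.append("!")
        elif tok[0] == "PRUNE":
            parts.append("~")
        elif tok[0] == "INDEX":
            parts.append(str(tok[1]))
        else:
            parts.append(f"{tok[1]}-{tok[2]}")
    return ",".join(parts)


def parse_selection(expr: str, n: int, current=None, data: RDCSet | None = None):
    """Apply a selection expression to a mask of ``n`` equations.

    All-or-nothing: a malformed or out-of-range token raises before any part
    of the expression is applied.
    """
    if n < 1:
        raise SelectionError("selection needs at least one equation")
    sel = parse_expression(expr)
    for tok in sel.tokens:
        if tok[0] == "INDEX" and tok[1] > n:
            raise SelectionError(f"index {tok[1]} out of range 1..{n}")
        if tok[0] == "RANGE" and tok[2] > n:
            raise SelectionError(f"range {tok[1]}-{tok[2]} out of range 1..{n}")
        if tok[0] == "PRUNE" and data is None:
            raise SelectionError("'~' needs the data to know which rows are missing")
    mask = (np.ones(n, dtype=bool) if current is None
            else np.asarray(current, dtype=bool).copy())
    for tok in sel.tokens:
        if tok[0] == "STAR":
            mask[:] = True
        elif tok[0] == "NEGATE":
            mask = ~mask
        elif tok[0] == "PRUNE":
            for d in data.data:
                if d.missing:
                    mask[d.index - 1] = False
        elif tok[0] == "INDEX":
            mask[tok[1] - 1] = True
        else:
            mask[tok[1] - 1: tok[2]] = True
    return mask


# ---------------------------------------------------------------------------
# Session state

@dataclass
class SessionState:
    """A saveable snapshot: data, selections, and analysis parameters."""

    media: list[RDCSet]
    error_threshold: float | None = None
    n_trials: int = 200
    seed: int = 0
    provenance: dict = None

    def __post_init__(self):
        if self.provenance is None:
            self.provenance = {}


def _rdcset_to_dict(rdcs: RDCSet) -> dict:
    return {
        "medium_label": rdcs.medium_label,
        "selection": [bool(s) for s in rdcs.selection],
        "data": [
            {
                "coords_i": list(d.vector.coords_i),
                "coords_j": list(d.vector.coords_j),
                "d_obs": d.d_obs,
                "error": d.error,
                "dmax": d.dmax,
                "label": d.label,
                "missing": d.missing,
            }
            for d in rdcs.data
        ],
    }


def _rdcset_from_dict(obj: dict) -> RDCSet:
    data = [
        RDCDatum(
            vector=make_vector(row["coords_i"], row["coords_j"]),
            d_obs=row["d_obs"], error=row["error"], dmax=row["dmax"],
            index=k + 1, label=row["label"], missing=row["missing"],
        )
        for k, row in enumerate(obj["data"])
    ]
    return RDCSet(data=data, selection=np.array(obj["selection"], dtype=bool),
                  medium_label=obj["medium_label"])


def save_state(state: SessionState, path) -> None:
    """Serialize a session to canonical JSON (sorted keys, UTF-8)."""
    payload = {
        "schema_version": STATE_SCHEMA_VERSION,
        "media": [_rdcset_to_dict(m) for m in state.media],
        "error_threshold": state.error_threshold,
        "n_trials": state.n_trials,
        "seed": state.seed,
        "provenance": state.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_state(path) -> SessionState:
    """Load a session saved by :func:`save_state`.

    Unknown future keys are preserved in ``provenance['extra_keys']``; a
    schema version newer than supported raises explicitly.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DataFileError(f"{path}: corrupt state file: {exc}") from exc
    version = payload.get("schema_version")
    if version is None or version > STATE_SCHEMA_VERSION:
        raise DataFileError(
            f"{path}: unsupported state schema version {version!r} "
            f"(supported <= {STATE_SCHEMA_VERSION})"
        )
    known = {"schema_version", "media", "error_threshold", "n_trials", "seed",
             "provenance"}
    provenance = dict(payload.get("provenance") or {})
    extra = {k: payload[k] for k in payload if k not in known}
    if extra:
        provenance["extra_keys"] = extra
    return SessionState(
        media=[_rdcset_from_dict(m) for m in payload["media"]],
        error_threshold=payload.get("error_threshold"),
        n_trials=payload.get("n_trials", 200),
        seed=payload.get("seed", 0),
        provenance=provenance,
    )


def read_ensemble_file(path) -> list[str]:
    """Read a list of data-file paths, one per non-blank line.

    '#' comments and blank lines are skipped; relative entries resolve
    against the ensemble file's own directory.
    """
    base = os.path.dirname(os.path.abspath(str(path)))
    paths = []
    with open(path) as fh:
        for line in fh:
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            if not os.path.isabs(entry):
                entry = os.path.join(base, entry)
            paths.append(entry)
    if not paths:
        import warnings

        warnings.warn(f"{path}: empty ensemble file", UserWarning, stacklevel=2)
    return paths
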