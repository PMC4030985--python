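"""Native-structure handling: Cα traces, secondary structure and contact maps.

The whole toolkit works at single-bead (Cα) resolution.  This module turns a
PDB document into a :class:`CaTrace` (one bead per resolved residue, with a
helix/sheet/coil label) and derives the :class:`NativeContactMap` that the
force field, the reaction coordinate and the analysis layers all share.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Accepted span for consecutive Cα–Cα distances in a native input (Å).
BOND_RANGE = (2.5, 4.5)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1 = "ACDEFGHIKLMNPQRSTVWY"


class EmptySelectionError(ValueError):
    """No CA atoms found for the requested chain/model."""


@dataclass
class CaTrace:
    """Ordered Cα bead chain for a single protein chain.

    positions are in Å; ``residue_index`` is the internal 1-based numbering
    with no gaps, ``author_resid`` keeps the PDB author numbering so that
    HELIX/SHEET records can be mapped back onto the trace.
    """

    positions: np.ndarray              # (n, 3) float64, Å
    residue_type: list[str]            # one-letter codes, "X" for unknown
    ss_label: list[str]                # "helix" | "sheet" | "coil"
    chain_id: str = "A"
    author_resid: np.ndarray | None = None
    chain_breaks: list[int] = field(default_factory=list)  # bead i where i->i+1 broken

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        n = len(self.positions)
        if len(self.residue_type) != n or len(self.ss_label) != n:
            raise ValueError("residue_type/ss_label length mismatch")
        if self.author_resid is None:
            self.author_resid = np.arange(1, n + 1)
        self.author_resid = np.asarray(self.author_resid, dtype=int)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def residue_index(self) -> np.ndarray:
        """Internal 1-based indices (contiguous by construction)."""
        return np.arange(1, self.n_beads + 1)

    def validate_native(self) -> None:
        """Enforce the invariants required of a structure used as native."""
        if self.n_beads < 4:
            raise ValueError(f"native trace needs >= 4 residues, got {self.n_beads}")
        d = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        lo, hi = BOND_RANGE
        ok = (d >= lo) & (d <= hi)
        bad = np.nonzero(~ok)[0]
        real_breaks = [i for i in bad if i not in self.chain_breaks]
        if real_breaks:
            raise ValueError(
                f"consecutive-bead distance outside [{lo}, {hi}] A at bead(s) "
                f"{[i + 1 for i in real_breaks]}"
            )


@dataclass
class NativeContactMap:
    """Set of native Cα–Cα contacts with per-pair metadata.

    Pairs are stored once with i < j (0-based bead indices).  ``ss_class``
    is "alpha" when both residues are helical, "beta" when both are in
    strands, else "other".
    """

    pairs: np.ndarray                  # (m, 2) int, i < j, 0-based
    native_distance: np.ndarray        # (m,) Å
    ss_class: np.ndarray               # (m,) of {"alpha", "beta", "other"}
    cutoff: float
    min_seq_sep: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.native_distance = np.asarray(self.native_distance, dtype=float)
        self.ss_class = np.asarray(self.ss_class, dtype=object)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def class_mask(self, name: str) -> np.ndarray:
        return self.ss_class == name


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _read_structure(pdb_document: str) -> gemmi.Structure:
    if "\n" not in pdb_document and (
        pdb_document.endswith(".pdb") or pdb_document.endswith(".ent")
    ):
        with open(pdb_document) as fh:
            pdb_document = fh.read()
    st = gemmi.read_pdb_string(pdb_document)
    st.setup_entities()
    return st


def load_ca_trace(
    pdb_document: str,
    chain_selector: str | None = None,
    model_selector: int = 1,
) -> CaTrace:
    """Extract the Cα trace of one chain from a PDB document.

    ``pdb_document`` may be a path or the PDB text itself.  Alternate
    locations are resolved to the highest-occupancy CA; residues missing a
    CA atom are skipped with a warning.  A consecutive-bead distance above
    4.5 Å is annotated as a chain break (warning), not a failure.
    """
    st = _read_structure(pdb_document)
    if len(st) == 0:
        raise EmptySelectionError("document contains no models")
    try:
        model = st[model_selector - 1]
    except IndexError:
        raise EmptySelectionError(f"no model {model_selector}") from None

    chains = [ch.name for ch in model]
    if not chains:
        raise EmptySelectionError("document contains no chains")
    if chain_selector is None:
        if len(chains) != 1:
            raise ValueError(
                f"multiple chains {chains}: select one explicitly"
            )
        chain_selector = chains[0]
    if chain_selector not in chains:
        raise EmptySelectionError(
            f"chain {chain_selector!r} not in document (has {chains})"
        )
    chain = model[chain_selector]

    positions, restypes, author = [], [], []
    for res in chain:
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            if res.name in AA3_TO_1:
                logger.warning("residue %s %s has no CA; skipped", res.name, res.seqid.num)
            continue
        ca = max(cas, key=lambda a: a.occ)
        positions.append([ca.pos.x, ca.pos.y, ca.pos.z])
        restypes.append(AA3_TO_1.get(res.name, "X"))
        author.append(res.seqid.num)

    if not positions:
        raise EmptySelectionError(f"no CA atoms for chain {chain_selector!r}")

    positions = np.asarray(positions)
    breaks: list[int] = []
    if len(positions) > 1:
        d = np.linalg.norm(np.diff(positions, axis=0), axis=1)
        for i in np.nonzero(d > BOND_RANGE[1])[0]:
            logger.warning(
                "chain break: beads %d-%d are %.2f A apart", i + 1, i + 2, d[i]
            )
            breaks.append(int(i))

    return CaTrace(
        positions=positions,
        residue_type=restypes,
        ss_label=["coil"] * len(positions),
        chain_id=chain_selector,
        author_resid=np.asarray(author),
        chain_breaks=breaks,
    )


def _ranges_from_records(st: gemmi.Structure, chain_id: str):
    helix_ranges, sheet_ranges = [], []
    for h in st.helices:
        if h.start.chain_name == chain_id:
            helix_ranges.append((h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain_id:
                sheet_ranges.append(
                    (strand.start.res_id.seqid.num, strand.end.res_id.seqid.num)
                )
    return helix_ranges, sheet_ranges


def assign_secondary_structure(pdb_document: str, trace: CaTrace) -> CaTrace:
    """Label trace residues helix/sheet/coil.

    HELIX/SHEET records (author numbering) take precedence; when the
    document carries none, a geometric fallback based on Cα virtual
    bend angles and torsions is used.  Record ranges that reference
    residues absent from the trace are clipped with a warning.
    """
    st = _read_structure(pdb_document)
    helix_ranges, sheet_ranges = _ranges_from_records(st, trace.chain_id)

    if not helix_ranges and not sheet_ranges:
        labels = geometric_ss_labels(trace.positions)
        trace.ss_label = labels
        return trace

    resid = trace.author_resid
    labels = ["coil"] * trace.n_beads
    known = set(resid.tolist())
    for kind, ranges in (("helix", helix_ranges), ("sheet", sheet_ranges)):
        for lo, hi in ranges:
            if lo not in known or hi not in known:
                logger.warning(
                    "%s record %d-%d partially outside trace; clipped", kind, lo, hi
                )
            sel = np.nonzero((resid >= lo) & (resid <= hi))[0]
            for i in sel:
                labels[i] = kind
    trace.ss_label = labels
    return trace


def _virtual_angles(x: np.ndarray):
    """Per-residue Cα pseudo bend angle theta(i-1,i,i+1) and torsion
    tau(i-1,i,i+1,i+2), degrees; NaN where undefined."""
    n = len(x)
    theta = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    for i in range(1, n - 1):
        a, b = x[i - 1] - x[i], x[i + 1] - x[i]
        c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        theta[i] = math.degrees(math.acos(np.clip(c, -1, 1)))
    for i in range(1, n - 2):
        b0 = x[i] - x[i - 1]
        b1 = x[i + 1] - x[i]
        b2 = x[i + 2] - x[i + 1]
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / np.linalg.norm(b1))
        xv = np.dot(n1, n2)
        yv = np.dot(m1, n2)
        tau[i] = math.degrees(math.atan2(yv, xv))
    return theta, tau


def geometric_ss_labels(x: np.ndarray) -> list[str]:
    """Fallback secondary-structure assignment from Cα geometry alone.

    An ideal α-helix has a virtual bend angle near 91° and virtual torsion
    magnitude near 50° (the sign tracks helix handedness); extended β
    geometry is flatter (bend ≥ 105°) with torsion near ±180°.  Windows
    are deliberately generous: this is a coarse classifier for CA-only
    files, not a DSSP replacement.
    """
    n = len(x)
    theta, tau = _virtual_angles(x)
    labels = ["coil"] * n
    for i in range(n):
        th, ta = theta[i], tau[i]
        if np.isnan(th):
            continue
        if 75 <= th <= 105 and (not np.isnan(ta)) and 20 <= abs(ta) <= 80:
            labels[i] = "helix"
        elif th >= 105 and (np.isnan(ta) or abs(ta) >= 120):
            labels[i] = "sheet"
    # smooth single-residue gaps inside runs
    for i in range(1, n - 1):
        if labels[i - 1] == labels[i + 1] != labels[i]:
            labels[i] = labels[i - 1]
    return labels


def build_contact_map(
    trace: CaTrace, cutoff_A: float = 7.5, min_seq_sep: int = 3
) -> NativeContactMap:
    """Native contacts: all bead pairs with distance <= cutoff and j−i >= sep."""
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    if min_seq_sep < 1:
        raise ValueError("min_seq_sep must be >= 1")
    x = trace.positions
    n = len(x)
    ii, jj = np.triu_indices(n, k=min_seq_sep)
    d = np.linalg.norm(x[ii] - x[jj], axis=1)
    keep = d <= cutoff_A
    ii, jj, d = ii[keep], jj[keep], d[keep]
    ss = np.asarray(trace.ss_label, dtype=object)
    cls = np.where(
        (ss[ii] == "helix") & (ss[jj] == "helix"),
        "alpha",
        np.where((ss[ii] == "sheet") & (ss[jj] == "sheet"), "beta", "other"),
    )
    return NativeContactMap(
        pairs=np.stack([ii, jj], axis=1),
        native_distance=d,
        ss_class=cls,
        cutoff=cutoff_A,
        min_seq_sep=min_seq_sep,
    )


# ---------------------------------------------------------------------------
# Writers / serialization
# ---------------------------------------------------------------------------

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


def write_ca_pdb(trace_or_positions, path_or_buf=None, *, residue_type=None,
                 chain_id="A", models=None) -> str | None:
    """Write a minimal CA-only PDB (single chain; multi-model if ``models``
    is a (m, n, 3) stack).  Returns the text when no destination is given."""
    if isinstance(trace_or_positions, CaTrace):
        tr = trace_or_positions
        coords = tr.positions[None] if models is None else np.asarray(models)
        restypes, chain_id = tr.residue_type, tr.chain_id
    else:
        coords = np.asarray(trace_or_positions, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        restypes = residue_type or ["GLY"] * coords.shape[1]
        restypes = [r if len(r) == 3 else AA1_TO_3.get(r, "GLY") for r in restypes]
    if isinstance(trace_or_positions, CaTrace):
        restypes = [AA1_TO_3.get(r, "GLY") for r in restypes]

    buf = io.StringIO()
    multi = coords.shape[0] > 1
    for m, frame in enumerate(coords, start=1):
        if multi:
            buf.write(f"MODEL     {m:4d}\n")
        for i, (xyz, res) in enumerate(zip(frame, restypes), start=1):
            buf.write(
                f"ATOM  {i:5d}  CA  {res:3s} {chain_id}{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           C\n"
            )
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    text = buf.getvalue()
    if path_or_buf is None:
        return text
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    return None


def model_to_json(trace: CaTrace, cmap: NativeContactMap) -> str:
    """Serialize trace + contact map to a documented JSON structure."""
    doc = {
        "format": "knotfold-model/1",
        "chain_id": trace.chain_id,
        "residue_type": list(trace.residue_type),
        "ss_label": list(trace.ss_label),
        "author_resid": trace.author_resid.tolist(),
        "positions": np.round(trace.positions, 4).tolist(),
        "contacts": {
            "cutoff": cmap.cutoff,
            "min_seq_sep": cmap.min_seq_sep,
            "pairs": cmap.pairs.tolist(),
            "native_distance": np.round(cmap.native_distance, 4).tolist(),
            "ss_class": cmap.ss_class.tolist(),
        },
    }
    return json.dumps(doc, indent=1)


def model_from_json(text: str) -> tuple[CaTrace, NativeContactMap]:
    doc = json.loads(text)
    if doc.get("format") != "knotfold-model/1":
        raise ValueError("not a knotfold model file")
    trace = CaTrace(
        positions=np.asarray(doc["positions"], dtype=float),
        residue_type=list(doc["residue_type"]),
        ss_label=list(doc["ss_label"]),
        chain_id=doc["chain_id"],
        author_resid=np.asarray(doc["author_resid"]),
    )
    c = doc["contacts"]
    cmap = NativeContactMap(
        pairs=np.asarray(c["pairs"]),
        native_distance=np.asarray(c["native_distance"]),
        ss_class=np.asarray(c["ss_class"], dtype=object),
        cutoff=c["cutoff"],
        min_seq_sep=c["min_seq_sep"],
    )
    return trace, cmap
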