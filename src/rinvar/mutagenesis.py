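"""In-silico point mutagenesis by idealized side-chain replacement.

A mutant structure is produced from a wild-type structure by swapping one
residue's side chain for a canonical-conformer template of the target amino
acid, rebuilt in the local backbone frame.  Backbone atoms are preserved
bit-for-bit; no energy minimization, rotamer search or backbone remodelling
is performed, so the result is a deterministic geometric hypothesis rather
than a refined model.  Steric clashes introduced by the rigid template are
reported, never repaired.

Templates are Chemical Component Dictionary ideal-geometry heavy atoms,
shipped as packaged JSON; users may substitute their own coordinates.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import (
    AA_ONE_TO_THREE,
    AA_THREE_TO_ONE,
    STANDARD_AA,
    Atom,
    Residue,
    Structure,
    StructureError,
)

__all__ = [
    "MutationSpec",
    "MutationError",
    "ProlineBackboneWarning",
    "StericClashWarning",
    "parse_mutation_label",
    "load_templates",
    "mutate",
    "CLASH_DISTANCE",
]

#: non-bonded heavy-atom pairs closer than this are reported as clashes (Å)
CLASH_DISTANCE = 2.0

_BACKBONE = ("N", "CA", "C", "O", "OXT")

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationError(ValueError):
    """Mutation cannot be applied (missing residue, identity mismatch...)."""


class ProlineBackboneWarning(UserWarning):
    """Mutation to or from proline: the backbone ring is not re-closed."""


class StericClashWarning(UserWarning):
    """Template placement produced non-bonded heavy atoms closer than 2.0 Å."""


@dataclass(frozen=True)
class MutationSpec:
    """One point substitution: chain/position plus WT and mutant residue type."""

    chain_id: str
    seq_num: int
    wt_aa: str
    mut_aa: str
    icode: str = ""
    label: str = ""

    def __post_init__(self):
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in STANDARD_AA:
                raise MutationError(f"{aa!r} is not a standard three-letter code")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{AA_THREE_TO_ONE[self.wt_aa]}{self.seq_num}{AA_THREE_TO_ONE[self.mut_aa]}",
            )

    @property
    def is_null(self) -> bool:
        return self.wt_aa == self.mut_aa


def parse_mutation_label(label: str, chain_id: str = "A", icode: str = "") -> MutationSpec:
    """Parse compact variant notation like ``"I848T"`` into a :class:`MutationSpec`.

    Grammar: one-letter WT code, residue number, one-letter mutant code.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise MutationError(
            f"malformed mutation label {label!r} (expected e.g. 'I848T')"
        )
    wt1, num, mut1 = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt1 not in AA_ONE_TO_THREE or mut1 not in AA_ONE_TO_THREE:
        raise MutationError(f"unknown one-letter amino-acid code in {label!r}")
    return MutationSpec(
        chain_id=chain_id,
        seq_num=num,
        wt_aa=AA_ONE_TO_THREE[wt1],
        mut_aa=AA_ONE_TO_THREE[mut1],
        icode=icode,
        label=label.strip(),
    )


_TEMPLATES: dict | None = None


def load_templates(path: str | Path | None = None) -> dict:
    """Load side-chain templates: ``{aa: {"coords": {atom: xyz}, "sidechain_order": [...]}}``."""
    global _TEMPLATES
    if path is None:
        if _TEMPLATES is None:
            text = resources.files("rinvar.data").joinpath("sidechain_templates.json").read_text()
            _TEMPLATES = json.loads(text)
        return _TEMPLATES
    return json.loads(Path(path).read_text())


def _frame(origin: np.ndarray, x_to: np.ndarray, plane: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame: x toward ``x_to``, ``plane`` in the xy plane."""
    x = x_to - origin
    x = x / np.linalg.norm(x)
    p = plane - origin
    y = p - np.dot(p, x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def mutate(
    s: Structure,
    m: MutationSpec,
    templates: dict | None = None,
    allow_null: bool = False,
) -> Structure:
    """Return a deep-copied structure with one residue's side chain replaced.

    The target residue keeps its backbone atoms (N, CA, C, O) untouched and,
    when both residue types have one, its CB; remaining side-chain atoms are
    placed from the template in the local N-CA-CB frame (or by N/CA/C
    superposition when no CB exists, e.g. mutating glycine).  All other
    residues are untouched.

    Raises :class:`MutationError` when the residue is absent or its type does
    not match ``m.wt_aa``.  Null mutations (X→X) require ``allow_null`` and
    return an unmodified copy.
    """
    if templates is None:
        templates = load_templates()
    res = s.residue(m.chain_id, m.seq_num, m.icode)
    if res is None:
        raise MutationError(
            f"residue {m.chain_id}:{m.seq_num}{m.icode} not found in structure {s.id!r}"
        )
    if res.aa != m.wt_aa:
        raise MutationError(
            f"wild-type mismatch at {m.chain_id}:{m.seq_num}: found {res.aa}, expected {m.wt_aa}"
        )
    if m.is_null and not allow_null:
        raise MutationError(f"null mutation {m.label!r} (pass allow_null=True to permit)")

    out = s.copy()
    if m.is_null:
        return out
    target = out.residue(m.chain_id, m.seq_num, m.icode)
    assert target is not None

    for name in ("N", "CA", "C"):
        if target.atom(name) is None:
            raise MutationError(
                f"residue {m.chain_id}:{m.seq_num} lacks backbone atom {name}; cannot mutate"
            )
    if "PRO" in (m.wt_aa, m.mut_aa):
        warnings.warn(
            f"{m.label}: mutation involving proline; backbone ring is not re-closed",
            ProlineBackboneWarning,
            stacklevel=2,
        )

    tpl = templates[m.mut_aa]
    tcoords = {k: np.asarray(v, float) for k, v in tpl["coords"].items()}
    side_order = [a for a in tpl["sidechain_order"]]

    backbone = [a for a in target.atoms if a.name in _BACKBONE]
    wt_cb = target.atom("CB")
    keep_cb = wt_cb is not None and "CB" in tcoords

    new_side: list[Atom] = []
    if keep_cb:
        new_side.append(wt_cb)
        n, ca = target.atom("N").coords, target.atom("CA").coords
        rot = _frame(ca, wt_cb.coords, n) @ _frame(
            tcoords["CA"], tcoords["CB"], tcoords["N"]
        ).T
        origin_act, origin_tpl = ca, tcoords["CA"]
        to_place = [a for a in side_order if a != "CB"]
    else:
        act = np.array([target.atom(x).coords for x in ("N", "CA", "C")])
        ref = np.array([tcoords[x] for x in ("N", "CA", "C")])
        origin_act, origin_tpl = act.mean(axis=0), ref.mean(axis=0)
        rotation, _ = Rotation.align_vectors(act - origin_act, ref - origin_tpl)
        rot = rotation.as_matrix()
        to_place = side_order

    for name in to_place:
        pos = origin_act + rot @ (tcoords[name] - origin_tpl)
        element = name[0] if name[0] in "CNOS" else name[:2]
        new_side.append(Atom(name=name, element=element, coords=pos))

    target.aa = m.mut_aa
    target.atoms = backbone + new_side

    _warn_clashes(out, target, [a for a in new_side if a is not wt_cb], m.label)
    return out


def _warn_clashes(s: Structure, target: Residue, placed: list[Atom], label: str) -> None:
    clashes = []
    for res in s.residues:
        if res is target:
            continue
        for a in res.heavy_atoms():
            for b in placed:
                d = a.distance(b)
                if d < CLASH_DISTANCE:
                    clashes.append((res.key, a.name, b.name, round(d, 2)))
    if clashes:
        warnings.warn(
            f"{label}: {len(clashes)} steric clash(es) < {CLASH_DISTANCE} Å after "
            f"template placement (not repaired): {clashes[:5]}",
            StericClashWarning,
            stacklevel=3,
        )
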