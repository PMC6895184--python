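"""Rule-based opto-electronic molecule filter.

Candidate structures pass through five ordered rules:

1.  *sanitize* — strip invalid character tokens from the raw SMILES and
    canonicalize what remains;
2.  *composition* — reject metals and charged species (any nonzero formal
    charge, including zwitterions);
3.  *conjugation* — require an aromatic cycle or a conjugated path of at
    least two multiple bonds;
4.  *trim* — replace long saturated alkyl substituents on the chromophore
    with methyl groups (negligible effect on absorption, large effect on
    compute cost);
5.  *band* — count the electrons of the (trimmed) neutral molecule and
    assign a compute-cost band; molecules outside 50–370 electrons are
    rejected as too small or too expensive.

The filter short-circuits: a molecule failing rule k records no results for
later rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RULE_ORDER",
    "ACCEPT_BANDS",
    "FilterError",
    "SanitizeError",
    "ChargedMoleculeError",
    "RuleResult",
    "FilterReport",
    "sanitize_smiles",
    "composition_problems",
    "check_composition",
    "detect_conjugation",
    "trim_alkyl_chains",
    "electron_count",
    "assign_band",
    "run_filter",
]

RULE_ORDER = ("sanitize", "composition", "conjugation", "trim", "band")

#: Bands an accepted molecule may land in; outside -> rejected.
ACCEPT_BANDS = ("small", "medium", "large", "xlarge")

#: Electron-count bands: (name, lower, upper), inclusive bounds.
NEL_BANDS = (
    ("small", 50, 140),
    ("medium", 141, 220),
    ("large", 221, 300),
    ("xlarge", 301, 370),
)

#: Organic / organochalcogen palette; anything else counts as a (heavy) metal.
ALLOWED_ATOMIC_NUMBERS = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53})

#: Characters that can legitimately appear in a SMILES string.
_SMILES_ALPHABET_RE = re.compile(r"[A-Za-z0-9@+\-#=()\[\]\\/%.:~$*]")
_BRACKET_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")


class FilterError(ValueError):
    pass


class SanitizeError(FilterError):
    """The raw SMILES could not be cleaned into a parseable structure."""


class ChargedMoleculeError(FilterError):
    """Electron counting requires a neutral species."""


@dataclass
class RuleResult:
    passed: bool
    note: str = ""


@dataclass
class FilterReport:
    """Per-molecule trace of the five filter rules."""

    input_smiles: str
    canonical_smiles: str | None = None
    rule_results: dict[str, RuleResult] = field(default_factory=dict)
    nel: int | None = None
    band: str | None = None
    accepted: bool = False

    def failed_rule(self) -> str | None:
        for rule in RULE_ORDER:
            result = self.rule_results.get(rule)
            if result is not None and not result.passed:
                return rule
        return None

    def to_doc(self) -> dict:
        return {
            "input_smiles": self.input_smiles,
            "canonical_smiles": self.canonical_smiles,
            "rule_results": {
                k: {"passed": v.passed, "note": v.note}
                for k, v in self.rule_results.items()
            },
            "nel": self.nel,
            "band": self.band,
            "accepted": self.accepted,
        }


# ---------------------------------------------------------------------------
# Rule 1: sanitize
# ---------------------------------------------------------------------------


def _strip_invalid_characters(raw: str) -> str:
    """Drop characters outside the SMILES alphabet.

    An invalid character inside a bracket atom (e.g. ``[<S>]``) invalidates
    the whole bracket token, which is removed in one piece.
    """

    def clean_token(m: re.Match) -> str:
        token = m.group(0)
        inner = token[1:-1]
        if all(_SMILES_ALPHABET_RE.match(c) for c in inner):
            return token
        return ""

    cleaned = _BRACKET_TOKEN_RE.sub(clean_token, raw)
    return "".join(c for c in cleaned if _SMILES_ALPHABET_RE.match(c))


def sanitize_smiles(raw: str) -> str:
    """Clean and canonicalize a raw SMILES string; stable on re-application."""
    if not raw or not raw.strip():
        raise SanitizeError("empty SMILES string")
    cleaned = _strip_invalid_characters(raw.strip())
    if not cleaned:
        raise SanitizeError(f"nothing parseable remains after cleaning {raw!r}")
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise SanitizeError(f"unparseable SMILES after cleaning: {cleaned!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Rule 2: composition
# ---------------------------------------------------------------------------


def composition_problems(mol: Chem.Mol) -> list[str]:
    problems = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in ALLOWED_ATOMIC_NUMBERS:
            problems.append(f"disallowed element {atom.GetSymbol()}")
        if atom.GetFormalCharge() != 0:
            problems.append(
                f"formal charge {atom.GetFormalCharge():+d} on {atom.GetSymbol()}"
            )
    return problems


def check_composition(mol: Chem.Mol) -> bool:
    """Pass iff the molecule is metal-free and carries no formal charge."""
    return not composition_problems(mol)


# ---------------------------------------------------------------------------
# Rule 3: conjugation
# ---------------------------------------------------------------------------


def _multiple_bonds(mol: Chem.Mol):
    return [
        b
        for b in mol.GetBonds()
        if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
    ]


def detect_conjugation(mol: Chem.Mol) -> bool:
    """Pass iff an aromatic cycle exists, or two multiple bonds are linked
    through a single bond (an alternating conjugated path)."""
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return True
    multiple = _multiple_bonds(mol)
    for i, b1 in enumerate(multiple):
        ends1 = {b1.GetBeginAtomIdx(), b1.GetEndAtomIdx()}
        for b2 in multiple[i + 1:]:
            ends2 = {b2.GetBeginAtomIdx(), b2.GetEndAtomIdx()}
            if ends1 & ends2:
                continue  # cumulated, not conjugated
            for a1 in ends1:
                for a2 in ends2:
                    link = mol.GetBondBetweenAtoms(a1, a2)
                    if link is not None and link.GetBondType() == Chem.BondType.SINGLE:
                        return True
    return False


# ---------------------------------------------------------------------------
# Rule 4: alkyl-chain trimming
# ---------------------------------------------------------------------------


def _chain_atom(atom: Chem.Atom) -> bool:
    return (
        atom.GetAtomicNum() == 6
        and not atom.GetIsAromatic()
        and not atom.IsInRing()
        and atom.GetFormalCharge() == 0
        and all(b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds())
    )


def _conjugated_atoms(mol: Chem.Mol) -> set[int]:
    conj = {a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()}
    for b in _multiple_bonds(mol):
        conj.add(b.GetBeginAtomIdx())
        conj.add(b.GetEndAtomIdx())
    return conj


def trim_alkyl_chains(mol: Chem.Mol) -> Chem.Mol:
    """Replace saturated carbon-only substituent chains of >= 2 atoms with a
    methyl group, when the chain hangs off (or next to) the conjugated system.

    Ring atoms, heteroatom-bearing chains and chains bridging two fragments
    are left untouched.  Idempotent.
    """
    chain = {a.GetIdx() for a in mol.GetAtoms() if _chain_atom(a)}
    if not chain:
        return mol
    conj = _conjugated_atoms(mol)

    # connected components of the chain-atom subgraph
    seen: set[int] = set()
    components: list[set[int]] = []
    for start in chain:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            idx = stack.pop()
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in chain and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        components.append(comp)

    to_delete: list[int] = []
    for comp in components:
        if len(comp) < 2:
            continue
        anchors = {
            nbr.GetIdx()
            for idx in comp
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors()
            if nbr.GetIdx() not in comp
        }
        if len(anchors) != 1:
            continue  # terminal fragment or a bridge between two fragments
        anchor = anchors.pop()
        anchor_atom = mol.GetAtomWithIdx(anchor)
        near_conjugation = anchor in conj or any(
            nbr.GetIdx() in conj for nbr in anchor_atom.GetNeighbors()
        )
        if not near_conjugation:
            continue
        keep = next(
            idx
            for idx in comp
            if any(nbr.GetIdx() == anchor for nbr in mol.GetAtomWithIdx(idx).GetNeighbors())
        )
        to_delete.extend(comp - {keep})

    if not to_delete:
        return mol
    rw = Chem.RWMol(mol)
    for idx in sorted(to_delete, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


# ---------------------------------------------------------------------------
# Rule 5: electron counting and banding
# ---------------------------------------------------------------------------


def electron_count(mol: Chem.Mol) -> int:
    """Total electrons of the neutral molecule: sum of atomic numbers,
    implicit hydrogens included."""
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        raise ChargedMoleculeError("electron count requires a neutral molecule")
    with_h = Chem.AddHs(mol)
    return sum(a.GetAtomicNum() for a in with_h.GetAtoms())


def assign_band(nel: int) -> str:
    """Partition the electron count into compute-cost bands (no gaps)."""
    if nel < 1:
        raise ValueError(f"nel must be >= 1, got {nel}")
    for name, lo, hi in NEL_BANDS:
        if lo <= nel <= hi:
            return name
    return "too_small" if nel < NEL_BANDS[0][1] else "too_large"


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def run_filter(smiles: str) -> FilterReport:
    """Apply the five rules in order, short-circuiting on first failure."""
    report = FilterReport(input_smiles=smiles)

    try:
        canonical = sanitize_smiles(smiles)
    except SanitizeError as exc:
        report.rule_results["sanitize"] = RuleResult(False, str(exc))
        return report
    report.rule_results["sanitize"] = RuleResult(True)
    report.canonical_smiles = canonical
    mol = Chem.MolFromSmiles(canonical)

    problems = composition_problems(mol)
    if problems:
        report.rule_results["composition"] = RuleResult(False, "; ".join(problems))
        return report
    report.rule_results["composition"] = RuleResult(True)
    # a multi-fragment survivor of the composition rule keeps its largest
    # fragment only (salts carry charges and have already failed)
    mol = _largest_fragment(mol)

    if not detect_conjugation(mol):
        report.rule_results["conjugation"] = RuleResult(False, "no significant pi-conjugation")
        return report
    report.rule_results["conjugation"] = RuleResult(True)

    trimmed = trim_alkyl_chains(mol)
    changed = trimmed.GetNumAtoms() != mol.GetNumAtoms()
    report.rule_results["trim"] = RuleResult(
        True, "alkyl chains trimmed to methyl" if changed else "nothing to trim"
    )
    report.canonical_smiles = Chem.MolToSmiles(trimmed)

    report.nel = electron_count(trimmed)
    report.band = assign_band(report.nel)
    in_range = report.band in ACCEPT_BANDS
    report.rule_results["band"] = RuleResult(
        in_range, f"NEL={report.nel} -> {report.band}"
    )
    report.accepted = in_range
    return report
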