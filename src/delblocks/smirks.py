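"""Protecting-group removal for building-block SMILES.

Building blocks in selection exports sometimes carry the protecting groups
used during library synthesis (Fmoc/Boc on amines, methyl/ethyl esters on
acids) even though the final on-DNA product is deprotected.  Leaving them in
place would bias similarity calculations, so curation strips them with SMIRKS
transforms applied exhaustively in list order.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = ["DEFAULT_DEPROTECTION_SMIRKS", "compile_smirks", "deprotect_smiles"]

#: Default deprotection transforms, applied in this order.  Each entry is
#: (name, SMIRKS).  Fmoc and Boc carbamates are cleaved back to the free
#: amine; methyl and ethyl esters are hydrolysed to the carboxylic acid.
DEFAULT_DEPROTECTION_SMIRKS: tuple[tuple[str, str], ...] = (
    ("fmoc", "[NX3;H0,H1:1]C(=O)OCC1c2ccccc2-c2ccccc21>>[N:1]"),
    ("boc", "[NX3;H0,H1:1]C(=O)OC(C)(C)C>>[N:1]"),
    ("methyl_ester", "[CX3:1](=[O:2])[OX2][CH3]>>[C:1](=[O:2])[OX2H1]"),
    ("ethyl_ester", "[CX3:1](=[O:2])[OX2][CH2][CH3]>>[C:1](=[O:2])[OX2H1]"),
)

_MAX_APPLICATIONS = 20  # guards against pathological self-matching transforms


class SmirksConfigError(ValueError):
    """A configured SMIRKS string failed to compile."""


def compile_smirks(
    smirks: tuple[tuple[str, str], ...] | list[tuple[str, str]],
) -> list[tuple[str, AllChem.ChemicalReaction]]:
    """Compile (name, SMIRKS) pairs, raising :class:`SmirksConfigError` at
    startup rather than per-row if any entry is malformed."""
    compiled = []
    for name, pattern in smirks:
        try:
            rxn = AllChem.ReactionFromSmarts(pattern)
        except Exception as exc:  # rdkit raises bare ValueError subclasses
            raise SmirksConfigError(f"SMIRKS {name!r} failed to compile: {exc}") from exc
        if rxn is None:
            raise SmirksConfigError(f"SMIRKS {name!r} failed to compile")
        compiled.append((name, rxn))
    return compiled


def deprotect_smiles(
    smiles: str,
    compiled: list[tuple[str, AllChem.ChemicalReaction]],
) -> tuple[str | None, dict[str, int]]:
    """Apply each transform exhaustively in order to one building block.

    Returns the canonical SMILES of the fully deprotected molecule and a
    count of applications per transform name.  Returns ``(None, {})`` for
    unparsable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, {}
    applied: dict[str, int] = {}
    for name, rxn in compiled:
        for _ in range(_MAX_APPLICATIONS):
            products = rxn.RunReactants((mol,))
            if not products:
                break
            candidate = products[0][0]
            try:
                Chem.SanitizeMol(candidate)
            except Exception:
                break
            mol = candidate
            applied[name] = applied.get(name, 0) + 1
    return Chem.MolToSmiles(mol), applied
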