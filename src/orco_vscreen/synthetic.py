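"""Seeded generators for every input the screening pipeline consumes.

No public compound set is deposited for this problem, so all tests and
demonstrations run on synthetic stand-ins that emulate the study's data:

* a labeled training panel (default 58 actives / 25 inactives) whose actives
  carry latent substructural motifs from three chemotype families —
  substituted phenols/catechols (potent), cinnamate esters and
  cinnamaldehydes (intermediate), and cyclohexanol/terpenoid-like alcohols
  (weak) — with log-normal IC50s spanning tens of micromolar to low
  millimolar;
* a diverse decoy screening library (default 1280 compounds) in which a
  small minority bears the same motifs (hidden ground truth emitted
  separately so pipeline code cannot consume labels);
* noisy monotone-decreasing concentration-inhibition curves following the
  Hill form; and
* two-choice larval counts with binomial exclusions.

Everything is reproducible from the spec seed.  Potency correlates with
chemotype: weak actives sit near motif-free decoys in fingerprint space, so
a classifier trained on all actives separates less cleanly than one trained
on the potent subset — mirroring how real panels with wide potency ranges
behave.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import ACTIVE, INACTIVE, MoleculeRecord, MoleculeSet, standardize

# ---------------------------------------------------------------------------
# chemotype grammar

_ALKYL = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
    "C(C)C", "C(C)(C)C", "CC(C)C", "CCC(C)C", "CC(C)(C)C", "C(C)CC",
]
_RING_SUBS = _ALKYL + ["OC"]  # OC on an aromatic ring is a methoxy group

# (template, n_slots); slots are filled with substituent fragments
_PHENOL_TEMPLATES = [
    ("Oc1ccc({0})cc1", 1),
    ("Oc1cccc({0})c1", 1),
    ("Oc1ccccc1{0}", 1),
    ("Oc1ccc({0})cc1{1}", 2),
    ("Oc1cc({0})cc({1})c1", 2),
    ("Oc1c({0})cc({1})cc1", 2),
    ("Oc1ccc({0})c({1})c1", 2),
    ("Oc1ccc({0})cc1O", 1),
    ("Oc1cc({0})ccc1O", 1),
]
_CINNAMATE_TEMPLATES = [
    ("O=C(O{0})C=Cc1ccccc1", 1),
    ("O=C(O{0})C=Cc1ccc({1})cc1", 2),
    ("O=CC=Cc1ccc({0})cc1", 1),
    ("O=CC({0})=Cc1ccccc1", 1),
]
_CYCLOHEXANOL_TEMPLATES = [
    ("OC1CCC({0})CC1", 1),
    ("OC1CCCCC1{0}", 1),
    ("OC1CC({0})CCC1{1}", 2),
    ("OC1CCC({0})C({1})C1", 2),
]
_INACTIVE_TEMPLATES = [
    ("c1ccc({0})cc1", 1),
    ("Cc1ccc({0})cc1", 1),
    ("c1cc({0})ccc1{1}", 2),
    ("COc1ccc({0})cc1", 1),
    ("COc1ccccc1{0}", 1),
    ("{0}OC(=O){1}", 2),
    ("{0}C(=O){1}", 2),
    ("CCN(CC)C(=O)c1ccc({0})cc1", 1),
    ("CCN(CC)C(=O)c1cccc({0})c1", 1),
    ("CCOC(=O)c1ccc({0})cc1", 1),
    ("{0}OC(=O)c1ccc({1})cc1", 2),
    ("OCC{0}", 1),
    ("OC({0})C{1}", 2),
    ("CCOC{0}", 1),
    ("{0}COC{1}", 2),
    ("N#C{0}", 1),
    ("{0}N({1})CC", 2),
    ("C1CCC({0})CC1", 1),
    ("CC1CCC({0})CC1", 1),
    ("CC1CCC({0})CC1{1}", 2),
    ("c1ccncc1{0}", 1),
    ("c1ccoc1{0}", 1),
    ("CC(=O)N(C){0}", 1),
]

#: Activity-conferring substructure patterns (phenol OH, conjugated enal or
#: cinnamoyl carbonyl, hydroxyl on a saturated ring carbon).
DEFAULT_MOTIF_SMARTS = ("[OX2H]c1ccccc1", "C=CC=O", "[OX2H][CX4R]")

_FAMILIES = ("phenol", "cinnamate", "cyclohexanol")
_FAMILY_TEMPLATES = {
    "phenol": _PHENOL_TEMPLATES,
    "cinnamate": _CINNAMATE_TEMPLATES,
    "cyclohexanol": _CYCLOHEXANOL_TEMPLATES,
}
# log10(uM) offsets from the panel-wide potency location, by chemotype
_FAMILY_POTENCY_OFFSET = {"phenol": -0.8, "cinnamate": 0.0, "cyclohexanol": 0.8}

IC50_RANGE_UM = (5.0, 20000.0)


@dataclass(frozen=True)
class LibrarySpec:
    """Spec for synthetic training panels and screening libraries.

    ``potency_log_mu``/``potency_log_sigma`` describe the marginal log10(uM)
    IC50 distribution of generated actives; the defaults put roughly a third
    of the actives below the 500 uM potent-subset cutoff, matching a panel
    spanning tens of micromolar to low millimolar.  ``label_noise`` flips
    each training label independently with the given probability (default 0)
    and is the dial that degrades ground-truth separability.
    """

    n_actives: int = 58
    n_inactives: int = 25
    n_library: int = 1280
    motif_smarts: tuple[str, ...] = DEFAULT_MOTIF_SMARTS
    active_fraction_library: float = 0.05
    potency_log_mu: float = 3.0
    potency_log_sigma: float = 0.8
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_actives, self.n_inactives, self.n_library) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.active_fraction_library <= 1.0:
            raise ValueError("active_fraction_library must be in [0,1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0,1]")


def _motif_mols(smarts: Sequence[str]) -> list[Chem.Mol]:
    mols = []
    for s in smarts:
        m = Chem.MolFromSmarts(s)
        if m is None:
            raise ValueError(f"invalid motif SMARTS {s!r}")
        mols.append(m)
    return mols


def _bears_motif(smiles: str, motifs: Sequence[Chem.Mol]) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and any(mol.HasSubstructMatch(m) for m in motifs)


def _random_alkyl(rng: np.random.Generator, max_carbons: int = 8) -> str:
    """Random branched alkyl fragment; valence-safe by capping branch runs."""
    n = int(rng.integers(1, max_carbons + 1))
    smiles = "C"
    branches = 0
    for _ in range(n - 1):
        if branches < 2 and rng.random() < 0.3:
            smiles += "(C)"
            branches += 1
        else:
            smiles += "C"
            branches = 0
    return smiles


def _enumerate_structures(
    rng: np.random.Generator,
    templates: Sequence[tuple[str, int]],
    n: int,
    motifs: Sequence[Chem.Mol],
    require_motif: bool,
    taken: set[str],
    subs: Sequence[str] = _RING_SUBS,
) -> list[str]:
    """Draw ``n`` distinct canonical structures from a template grammar."""
    out: list[str] = []
    attempts = 0
    max_attempts = 500 * max(1, n)
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not enumerate {n} distinct structures (got {len(out)}); "
                "template grammar exhausted"
            )
        template, slots = templates[rng.integers(len(templates))]
        fills = [
            subs[rng.integers(len(subs))] if rng.random() < 0.5 else _random_alkyl(rng)
            for _ in range(slots)
        ]
        smiles = template.format(*fills)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in taken:
            continue
        if _bears_motif(canonical, motifs) != require_motif:
            continue
        taken.add(canonical)
        out.append(canonical)
    return out


def _family_counts(n: int) -> dict[str, int]:
    base, extra = divmod(n, len(_FAMILIES))
    return {f: base + (1 if i < extra else 0) for i, f in enumerate(_FAMILIES)}


def generate_training_set(spec: LibrarySpec) -> MoleculeSet:
    """Labeled training panel with embedded structure-activity signal.

    Actives are enumerated from motif-bearing scaffold grammars (phenols,
    cinnamates, cyclohexanols) and assigned log-normal IC50s whose location
    depends on chemotype; inactives come from motif-free scaffolds.  All
    structures are standardized before emission, so re-standardizing is a
    no-op.  Byte-identical output for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = _motif_mols(spec.motif_smarts)
    taken: set[str] = set()

    records: list[MoleculeRecord] = []
    offsets_sq = np.mean([v**2 for v in _FAMILY_POTENCY_OFFSET.values()])
    within_sd = float(np.sqrt(max(spec.potency_log_sigma**2 - offsets_sq, 0.04)))
    idx = 0
    for family, count in _family_counts(spec.n_actives).items():
        structures = _enumerate_structures(
            rng, _FAMILY_TEMPLATES[family], count, motifs, require_motif=True, taken=taken
        )
        for smiles in structures:
            idx += 1
            log_ic50 = rng.normal(spec.potency_log_mu + _FAMILY_POTENCY_OFFSET[family], within_sd)
            ic50 = float(np.clip(10.0**log_ic50, *IC50_RANGE_UM))
            records.append(
                MoleculeRecord(
                    id=f"A{idx:03d}",
                    structure=smiles,
                    source=f"synthetic:{family}",
                    label=ACTIVE,
                    ic50_um=round(ic50, 2),
                )
            )
    inactive_structures = _enumerate_structures(
        rng, _INACTIVE_TEMPLATES, spec.n_inactives, motifs, require_motif=False, taken=taken
    )
    for j, smiles in enumerate(inactive_structures, 1):
        records.append(
            MoleculeRecord(id=f"I{j:03d}", structure=smiles, source="synthetic:decoy", label=INACTIVE)
        )

    if spec.label_noise > 0:
        flipped = []
        flip = rng.random(len(records)) < spec.label_noise
        for rec, f in zip(records, flip):
            if not f:
                flipped.append(rec)
                continue
            new_label = INACTIVE if rec.label == ACTIVE else ACTIVE
            flipped.append(replace(rec, label=new_label, ic50_um=None))
        records = flipped

    return MoleculeSet([standardize(r) for r in records])


def generate_library(
    spec: LibrarySpec, spike_training: MoleculeSet | None = None
) -> tuple[MoleculeSet, pd.DataFrame]:
    """Decoy screening library with a motif-bearing minority.

    Returns the library plus a hidden-truth table (id, structure,
    is_motif_active, family) kept separate from the molecules so pipeline
    code cannot accidentally consume labels.  With ``spike_training`` the
    given training records are inserted (ids preserved and flagged),
    reproducing a catalog that contains previously tested compounds.
    """
    rng = np.random.default_rng(spec.seed + 1)
    motifs = _motif_mols(spec.motif_smarts)
    taken: set[str] = set()

    records: list[MoleculeRecord] = []
    truth_rows = []
    if spike_training is not None:
        for rec in spike_training.records:
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(rec.structure))
            taken.add(canonical)
            records.append(
                MoleculeRecord(id=rec.id, structure=rec.structure, source="spiked-training",
                               standardized=rec.standardized)
            )
            truth_rows.append(
                {
                    "id": rec.id,
                    "structure": canonical,
                    "is_motif_active": _bears_motif(canonical, motifs),
                    "family": "training",
                    "is_training": True,
                }
            )
    n_fresh = spec.n_library - len(records)
    if n_fresh < 0:
        raise ValueError("spiked training set larger than n_library")
    n_motif = int(round(n_fresh * spec.active_fraction_library))
    idx = 0
    for family, count in _family_counts(n_motif).items():
        for smiles in _enumerate_structures(
            rng, _FAMILY_TEMPLATES[family], count, motifs, require_motif=True, taken=taken
        ):
            idx += 1
            records.append(MoleculeRecord(id=f"LIB{idx:04d}", structure=smiles, source="synthetic:library"))
            truth_rows.append(
                {"id": f"LIB{idx:04d}", "structure": smiles, "is_motif_active": True,
                 "family": family, "is_training": False}
            )
    for smiles in _enumerate_structures(
        rng, _INACTIVE_TEMPLATES, n_fresh - n_motif, motifs, require_motif=False, taken=taken
    ):
        idx += 1
        records.append(MoleculeRecord(id=f"LIB{idx:04d}", structure=smiles, source="synthetic:library"))
        truth_rows.append(
            {"id": f"LIB{idx:04d}", "structure": smiles, "is_motif_active": False,
             "family": "decoy", "is_training": False}
        )

    standardized = [r if r.standardized else standardize(r) for r in records]
    return MoleculeSet(standardized), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# dose-response and behavior generators


@dataclass(frozen=True)
class DoseResponseSpec:
    """Ground truth for one synthetic concentration-inhibition experiment."""

    true_ic50: float = 48.0
    true_n: float = 1.0
    true_imax: float = 100.0
    # standard 8-point half-log dilution series bracketing the potency scale
    concentrations: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.true_ic50, self.true_n, self.true_imax) <= 0:
            raise ValueError("true parameters must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def generate_dose_response(spec: DoseResponseSpec, compound_id: str = "CPD1") -> pd.DataFrame:
    """Noisy Hill-curve assay rows matching the dose-response CSV schema.

    The sham-normalized percent response at concentration X is
    Imax / (1 + (X/IC50)^n) * (1 + eps) with eps ~ Normal(0, noise_cv),
    truncated at zero; currents are reconstructed so that the
    percent-of-control arithmetic recovers exactly that response.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for x in spec.concentrations:
        ideal = spec.true_imax / (1.0 + (x / spec.true_ic50) ** spec.true_n)
        response = max(0.0, ideal * (1.0 + rng.normal(0.0, spec.noise_cv)))
        pre = float(rng.normal(550.0, 30.0))  # nA; arbitrary healthy-oocyte scale
        sham = 100.0
        rows.append(
            {
                "compound_id": compound_id,
                "concentration_um": x,
                "i_pre1": pre,
                "i_pre2": pre,
                "i_test": pre * (response / 100.0) * (sham / 100.0),
                "sham_percent": sham,
            }
        )
    return pd.DataFrame(rows)


def generate_behavior_trial(
    n_larvae: int = 50, p_stim: float = 0.5, p_excluded: float = 0.0, seed: int = 0
):
    """Simulated two-choice plate: binomial exclusions, then side choice.

    ``excluded`` ~ Binomial(n_larvae, p_excluded); each remaining larva goes
    to the stimulus side independently with probability ``p_stim``.  Default
    plating count is 50 larvae.
    """
    from .assays import BehaviorTrial

    if not (0.0 <= p_stim <= 1.0 and 0.0 <= p_excluded <= 1.0):
        raise ValueError("probabilities must be in [0,1]")
    rng = np.random.default_rng(seed)
    excluded = int(rng.binomial(n_larvae, p_excluded))
    scored = n_larvae - excluded
    s_count = int(rng.binomial(scored, p_stim))
    return BehaviorTrial(s_count=s_count, c_count=scored - s_count, excluded=excluded)
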