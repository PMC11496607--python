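"""Deterministic toy solute/solvent datasets with known target functions.

The generator pairs small organic solutes from named structural families with
registry solvents and assigns targets that are exact closed-form functions of
the features the network can see. That makes every stage of the pipeline
testable end-to-end: with zero noise the targets are recoverable exactly, and
the variance split between solvent and solute terms yields a closed-form
ceiling on what any solvent-blind predictor can achieve.

Built-in target rules (constants ALPHA=10, BETA=5, GAMMA=3, chosen once so the
solvent and solute terms have comparable variance over the default pools):

* ``solvent_linear``    y = ALPHA * SdP(solvent) + BETA * n_aromatic + GAMMA * n_halogen
* ``solute_only``       y = BETA * n_aromatic + GAMMA * n_halogen
* ``marked_sensitive``  y = GAMMA * n_halogen + 0.2 * BETA * n_aromatic

SdP is the Catalan dipolarity coordinate of the solvent; n_aromatic and
n_halogen count aromatic and halogen heavy atoms of the solute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .featurize import (
    HALOGENS,
    DissolvedSample,
    FeaturizationError,
    SolventRegistry,
    build_sample,
    parse_smiles,
)

__all__ = [
    "ALPHA",
    "BETA",
    "GAMMA",
    "ToyDatasetSpec",
    "enumerate_solutes",
    "synth_target",
    "generate",
    "noiseless_targets",
    "signal_sd",
    "solute_only_ceiling",
]

ALPHA = 10.0  # target units per SdP unit
BETA = 5.0  # target units per aromatic atom
GAMMA = 3.0  # target units per halogen atom

SDP_INDEX = 2  # position of SdP in the (Et30, SP, SdP, SA, SB) polarity vector


# --------------------------------------------------------------------------
# solute grammars
# --------------------------------------------------------------------------
def _alkanes() -> list[str]:
    linear = ["C" * n for n in range(1, 9)]
    branched = [
        "CC(C)C", "CC(C)CC", "CC(C)(C)C", "CCC(C)CC", "CC(C)C(C)C",
        "CCCC(C)C", "CC(C)(C)CC", "CCC(C)(C)C", "CCC(C)CCC", "CC(C)CC(C)C",
    ]
    return linear + branched


def _alcohols() -> list[str]:
    return [
        "CO", "CCO", "CCCO", "CCCCO", "CCCCCO", "CCCCCCO",
        "CC(C)O", "CC(C)CO", "CCC(C)O", "CC(C)(C)O", "OCC(C)C", "CCCC(C)O",
    ]


def _halides() -> list[str]:
    out = []
    for x in sorted(HALOGENS):
        out += [f"C{x}", f"CC{x}", f"CCC{x}", f"{x}c1ccccc1"]
    out += ["ClCCl", "ClC(Cl)Cl", "ClC(Cl)(Cl)Cl", "FC(F)F", "FC(F)(F)F",
            "BrCBr", "FCCF", "ClCCCl", "FC(F)(F)c1ccccc1", "Clc1ccccc1Cl"]
    return out


def _aromatics() -> list[str]:
    return [
        "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Cc1ccccc1C", "Cc1cccc(C)c1",
        "Cc1ccc(C)cc1", "Oc1ccccc1", "COc1ccccc1", "CCCc1ccccc1",
        "c1ccc2ccccc2c1", "Cc1ccc(CC)cc1", "CC(C)c1ccccc1",
    ]


def _heteroaromatics() -> list[str]:
    return [
        "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "Cc1ccncc1",
        "Cc1ccco1", "Cc1cccs1", "c1cnccn1", "Cc1cc[nH]c1", "CCc1ccncc1",
    ]


GRAMMARS: dict[str, object] = {
    "alkanes": _alkanes,
    "alcohols": _alcohols,
    "halides": _halides,
    "aromatics": _aromatics,
    "heteroaromatics": _heteroaromatics,
    "mixed": lambda: _alkanes() + _alcohols() + _halides() + _aromatics() + _heteroaromatics(),
}


def enumerate_solutes(grammar: str, n: int, seed: int = 0) -> list[str]:
    """Draw n unique, parseable SMILES from a family, deterministically."""
    if grammar not in GRAMMARS:
        raise FeaturizationError(f"unknown solute grammar {grammar!r}; have {sorted(GRAMMARS)}")
    seen, pool = set(), []
    for smiles in GRAMMARS[grammar]():
        canonical = parse_smiles(smiles).canonical_smiles  # validates
        if canonical not in seen:
            seen.add(canonical)
            pool.append(smiles)
    if n > len(pool):
        raise FeaturizationError(
            f"grammar {grammar!r} holds only {len(pool)} unique molecules, {n} requested"
        )
    order = np.random.default_rng(seed).permutation(len(pool))
    return [pool[i] for i in order[:n]]


# --------------------------------------------------------------------------
# target rules
# --------------------------------------------------------------------------
def _counts(sample: DissolvedSample) -> tuple[int, int]:
    aromatic = int(sum(1 for row in sample.solute.environment if row[22] == 1.0))
    halogen = sum(1 for s in sample.solute.symbols if s in HALOGENS)
    return aromatic, halogen


def synth_target(sample: DissolvedSample, rule: str) -> float:
    """Exact closed-form target for a dissolved sample under a named rule."""
    aromatic, halogen = _counts(sample)
    sdp = float(sample.solvent_polarity[SDP_INDEX])
    if rule == "solvent_linear":
        return ALPHA * sdp + BETA * aromatic + GAMMA * halogen
    if rule == "solute_only":
        return BETA * aromatic + GAMMA * halogen
    if rule == "marked_sensitive":
        return GAMMA * halogen + 0.2 * BETA * aromatic
    raise FeaturizationError(f"unknown target rule {rule!r}")


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ToyDatasetSpec:
    n_samples: int = 200
    solvent_pool: tuple[str, ...] = ("H2O", "hexane", "DMSO", "toluene")
    solute_grammar: str = "mixed"
    target_rule: str = "solvent_linear"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.solvent_pool:
            raise ValueError("solvent_pool must be nonempty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rows(spec: ToyDatasetSpec, registry: SolventRegistry):
    """Deterministic (solute, solvent) pairing: solvents cycle fastest, so every
    solute meets every solvent as the dataset grows (no solute-solvent
    confounding a solvent-blind model could exploit)."""
    capacity = len({parse_smiles(s).canonical_smiles for s in GRAMMARS[spec.solute_grammar]()})
    solutes = enumerate_solutes(spec.solute_grammar, capacity, seed=spec.seed)
    pool = list(spec.solvent_pool)
    for i in range(spec.n_samples):
        solvent = pool[i % len(pool)]
        solute = solutes[(i // len(pool)) % len(solutes)]
        yield i, solute, solvent


def generate(
    spec: ToyDatasetSpec, out_path=None, registry: SolventRegistry | None = None
) -> pd.DataFrame:
    """Build the dataset CSV: rule targets plus N(0, noise_sd) noise, rows
    shuffled by the spec seed. Byte-identical across regenerations."""
    registry = registry or SolventRegistry.default()
    rng = np.random.default_rng(spec.seed)
    records = []
    for i, solute, solvent in _rows(spec, registry):
        sample = build_sample(solute, solvent, 0.0, registry=registry, sample_id=f"s{i:05d}")
        records.append((f"s{i:05d}", solute, solvent, synth_target(sample, spec.target_rule)))
    noise = rng.normal(0.0, spec.noise_sd, size=len(records)) if spec.noise_sd > 0 else 0.0
    frame = pd.DataFrame(records, columns=["sample_id", "solute_smiles", "solvent", "target"])
    frame["target"] = frame["target"].to_numpy() + noise
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    if out_path is not None:
        frame.to_csv(out_path, index=False, float_format="%.12g")
    return frame


def noiseless_targets(spec: ToyDatasetSpec, registry: SolventRegistry | None = None):
    """Rule values and their solvent/solute decomposition for the spec's rows."""
    registry = registry or SolventRegistry.default()
    totals, solvent_terms = [], []
    for i, solute, solvent in _rows(spec, registry):
        sample = build_sample(solute, solvent, 0.0, registry=registry, sample_id=str(i))
        y = synth_target(sample, spec.target_rule)
        sdp = float(sample.solvent_polarity[SDP_INDEX])
        s_term = ALPHA * sdp if spec.target_rule == "solvent_linear" else 0.0
        totals.append(y)
        solvent_terms.append(s_term)
    return np.array(totals), np.array(solvent_terms)


def signal_sd(spec: ToyDatasetSpec, registry: SolventRegistry | None = None) -> float:
    """Standard deviation of the noiseless targets (the 'signal')."""
    totals, _ = noiseless_targets(spec, registry)
    return float(totals.std())


def solute_only_ceiling(spec: ToyDatasetSpec, registry: SolventRegistry | None = None) -> float:
    """Closed-form R2 ceiling for any predictor blind to the solvent.

    Solute and solvent assignments are independent by construction, so the
    best solvent-blind predictor is E[y | solute]; its residual variance is the
    solvent-term variance plus the noise variance, giving

        R2_max = 1 - (Var(solvent term) + noise_sd^2) / (Var(y) + noise_sd^2).
    """
    totals, solvent_terms = noiseless_targets(spec, registry)
    var_total = float(totals.var()) + spec.noise_sd**2
    var_solvent = float(solvent_terms.var())
    if var_total == 0:
        return 0.0
    return 1.0 - (var_solvent + spec.noise_sd**2) / var_total
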