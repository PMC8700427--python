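"""Reference mutational-signature matrix (synthetic stand-in).

The signature-matching step compares NMF-extracted processes against a
96 x 30 reference matrix of known signature profiles indexed 1..30. The
bundled matrix (``data/signature_reference_synthetic.tsv``) is a SYNTHETIC
stand-in constructed by this module, not the published catalogue: it
emulates the qualitative shape of the well-known processes the pipeline
reasons about —

* signature 1: C>T concentrated at NpCpG contexts (5-methylcytosine
  deamination, ageing);
* signature 2: C>T at TpCpN (APOBEC);
* signature 3: near-uniform across all 96 classes (homologous-recombination
  repair deficiency, "BRCAness");
* signature 5: T>C-dominated, broad (aetiology unknown);
* signature 6: C>T at GpCpN plus elevated C>T overall (mismatch-repair
  deficiency);
* signature 13: C>G at TpCpN (APOBEC);

with the remaining 24 columns drawn from a seeded Dirichlet so matching has
realistic distractors. Columns sum to one. Generation is deterministic, so
the bundled TSV can be regenerated bit-identically with
:func:`build_reference_matrix`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import CONTEXTS_96

__all__ = [
    "STRUCTURED_SIGNATURES",
    "build_reference_matrix",
    "load_reference_matrix",
    "reference_path",
]

#: Signature indices with a structured (non-random) synthetic profile.
STRUCTURED_SIGNATURES = (1, 2, 3, 5, 6, 13)

_GENERATOR_SEED = 961230  # frozen: the reference is a fixture, not a dial


def _structured_profile(sig: int) -> np.ndarray:
    w = np.full(96, 0.05 / 96)
    labels = list(CONTEXTS_96)

    def add(mass: float, sub: str, five: str = "ACGT", three: str = "ACGT") -> None:
        hit = [
            i for i, lab in enumerate(labels)
            if lab[2:5] == sub and lab[0] in five and lab[6] in three
        ]
        w[hit] += mass / len(hit)

    if sig == 1:
        add(0.75, "C>T", three="G")
        add(0.10, "C>T")
        add(0.10, "T>C")
    elif sig == 2:
        add(0.85, "C>T", five="T")
        add(0.10, "C>G", five="T")
    elif sig == 3:
        # flat: the HRR-deficiency profile is famously featureless
        w = np.full(96, 1.0 / 96)
    elif sig == 5:
        add(0.55, "T>C")
        add(0.20, "C>T")
        add(0.20, "T>A")
    elif sig == 6:
        add(0.55, "C>T", five="G")
        add(0.25, "C>T")
        add(0.15, "C>A")
    elif sig == 13:
        add(0.85, "C>G", five="T")
        add(0.10, "C>T", five="T")
    else:
        raise ValueError(f"no structured profile for signature {sig}")
    return w / w.sum()


def build_reference_matrix() -> pd.DataFrame:
    """Deterministically construct the synthetic 96 x 30 reference matrix."""
    rng = np.random.default_rng(_GENERATOR_SEED)
    cols = {}
    structured = {i: _structured_profile(i) for i in STRUCTURED_SIGNATURES}
    for sig in range(1, 31):
        if sig in structured:
            w = structured[sig]
        else:
            # keep fillers away from the structured profiles so best-cosine
            # matching is unambiguous for the emulated processes
            for _ in range(200):
                w = rng.dirichlet(np.full(96, 0.25))
                cos = [
                    float(w @ s / (np.linalg.norm(w) * np.linalg.norm(s)))
                    for s in structured.values()
                ]
                if max(cos) < 0.70:
                    break
        cols[f"Signature.{sig}"] = w
    df = pd.DataFrame(cols, index=list(CONTEXTS_96))
    df.index.name = "context"
    return df


def reference_path() -> Path:
    return Path(resources.files("somamut").joinpath(
        "data/signature_reference_synthetic.tsv"))


def load_reference_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 96 x N signature reference TSV (context labels as first column).

    Validates the row labelling against the canonical 96-context order and
    column-normalises (defensively) to unit sums.
    """
    df = pd.read_csv(path if path is not None else reference_path(),
                     sep="\t", index_col=0)
    if list(df.index) != list(CONTEXTS_96):
        raise ValueError("signature reference rows must be the canonical "
                         "96 context labels in canonical order")
    return df.div(df.sum(axis=0), axis=1)


def write_reference_matrix(path: str | Path) -> None:
    build_reference_matrix().to_csv(path, sep="\t", float_format="%.8f")
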