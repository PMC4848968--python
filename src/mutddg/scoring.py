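"""Feature assembly and the regime-specific linear ddG models.

The predictor is affine in ten features.  Folded-minus-segment double
differences isolate the folding contribution of each energy term: for a term
E, ddE = [E(MT) - E(WT)] - [E(MT_segment) - E(WT_segment)], the 3-residue
segments standing in for the unfolded state.  The small-effect and
large-effect regimes (selected by the combined flag probability, threshold
0.5) use different published term sets and weights; a pooled "all" model
ignores the flags.

The bundled weights were fitted against experimental data with a different
energy stack (minimized structures, all-atom force field); with this
package's internal heavy-atom energies they are approximations, and the
training module exists to refit them.  Reports carry a weights_provenance
field for this reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from . import forcefield as ff
from .descriptors import compute_sasa
from .electrostatics import (
    DielectricModel,
    coulomb_energy,
    nonpolar_solvation,
    reaction_field_energy,
)
from .knowledge import FlagProbabilities, entropy_sum, site_entropy
from .mutate import MutationSpec, StructureQuartet
from .structure import ProteinStructure

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "d_ie", "dd_ie", "dd_ve", "dd_ee", "dd_sp",
    "d_s", "d_ssum", "sas_mt", "snsas_mt", "d_hydr",
)

#: term vocabulary per regime (the small regime additionally recognises dd_ie
#: for refitting even though the published set carries no weight for it)
REGIME_TERMS = {
    "small": ("d_ie", "dd_ie", "dd_ve", "dd_ee", "dd_sp", "d_ssum"),
    "large": ("dd_ve", "dd_ee", "dd_sp", "d_s", "d_ssum", "sas_mt", "snsas_mt"),
    "all": (
        "dd_ve", "dd_ee", "dd_sp", "d_s", "d_hydr", "d_ssum", "sas_mt", "snsas_mt",
    ),
}


@dataclass
class FeatureVector:
    d_ie: float = 0.0      # dIE, kcal/mol
    dd_ie: float = 0.0     # ddIE, kcal/mol
    dd_ve: float = 0.0     # ddVE, kcal/mol
    dd_ee: float = 0.0     # ddEE, kcal/mol
    dd_sp: float = 0.0     # ddSP, kcal/mol
    d_s: float = 0.0       # site entropy change, dimensionless
    d_ssum: float = 0.0    # total entropy change, dimensionless
    sas_mt: float = 0.0    # mutant total SASA, A^2
    snsas_mt: float = 0.0  # SN/SAS of the mutant, kcal/mol/A^2
    d_hydr: float = 0.0    # hydropathy difference, dimensionless

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


@dataclass
class WeightSet:
    regime: str
    intercept: float
    weights: Dict[str, float]
    pvalues: Dict[str, float] = field(default_factory=dict)
    provenance: str = "published"


def load_weight_sets(path: str | Path | None = None) -> Dict[str, WeightSet]:
    """The bundled published weight sets (or a refit TSV in the same schema)."""
    if path is None:
        text = (resources.files("mutddg") / "data" / "weights.tsv").read_text()
        provenance = "published"
    else:
        text = Path(path).read_text()
        provenance = str(path)
    df = pd.read_csv(pd.io.common.StringIO(text), sep="\t")
    out: Dict[str, WeightSet] = {}
    for regime in ("small", "large", "all"):
        wcol, pcol = regime, f"{regime}_p"
        weights: Dict[str, float] = {}
        pvals: Dict[str, float] = {}
        intercept = 0.0
        for _, row in df.iterrows():
            val = row[wcol]
            if isinstance(val, str) and val.strip() == "NA" or pd.isna(val):
                continue
            if row["term"] == "intercept":
                intercept = float(val)
            else:
                weights[row["term"]] = float(val)
            pv = row[pcol]
            if not (isinstance(pv, str) and pv.strip() == "NA") and not pd.isna(pv):
                pvals[row["term"]] = float(pv)
        out[regime] = WeightSet(regime, intercept, weights, pvals, provenance)
    return out


def save_weight_set(sets: Dict[str, WeightSet], path: str | Path) -> None:
    terms: list[str] = []
    for ws in sets.values():
        for t in ws.weights:
            if t not in terms:
                terms.append(t)
    rows = ["term\tsmall\tsmall_p\tlarge\tlarge_p\tall\tall_p"]
    regimes = ("small", "large", "all")

    def cell(regime: str, term: str, pv: bool) -> str:
        ws = sets.get(regime)
        if ws is None:
            return "NA"
        if term == "intercept":
            return "NA" if pv else f"{ws.intercept:.6g}"
        src = ws.pvalues if pv else ws.weights
        return f"{src[term]:.6g}" if term in src else "NA"

    for term in ["intercept"] + terms:
        cells = []
        for regime in regimes:
            cells.append(cell(regime, term, False))
            cells.append(cell(regime, term, True))
        rows.append(term + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


def assemble_features(
    quartet: StructureQuartet,
    mutation: MutationSpec,
    params: ff.ParameterSet | None = None,
    model: DielectricModel | None = None,
    pb_scale: float = 1.0,
    perfil: float = 0.70,
    pb_tol: float = 1e-6,
) -> FeatureVector:
    """Compute the ten regression features from the structure quartet."""
    params = params or ff.default_parameters()
    model = model or DielectricModel()
    structs = {
        "wt": quartet.wt,
        "mt": quartet.mt,
        "wt_seg": quartet.wt_segment,
        "mt_seg": quartet.mt_segment,
    }
    tops = {k: ff.build_topology(s, params) for k, s in structs.items()}

    ie = {k: ff.bonded_energy(s.coords(), tops[k]).internal for k, s in structs.items()}
    ve = {k: ff.vdw_energy(s, params, top=tops[k]) for k, s in structs.items()}
    ee = {k: coulomb_energy(s, params, model, top=tops[k]) for k, s in structs.items()}
    sp = {
        k: reaction_field_energy(
            s, params, model, scale=pb_scale, perfil=perfil, tol=pb_tol, top=tops[k]
        )
        for k, s in structs.items()
    }

    def ddiff(term: Dict[str, float]) -> float:
        return (term["mt"] - term["wt"]) - (term["mt_seg"] - term["wt_seg"])

    d_ie = ie["mt"] - ie["wt"]
    dd_ie = ddiff(ie)

    _, sas_mt = compute_sasa(quartet.mt, params)
    sn = nonpolar_solvation(sas_mt)

    d_s = site_entropy(
        quartet.mt, mutation.chain, mutation.seq, mutation.icode, params=params
    ) - site_entropy(
        quartet.wt, mutation.chain, mutation.seq, mutation.icode, params=params
    )
    d_ssum = entropy_sum(quartet.mt, params=params) - entropy_sum(
        quartet.wt, params=params
    )

    return FeatureVector(
        d_ie=d_ie,
        dd_ie=dd_ie,
        dd_ve=ddiff(ve),
        dd_ee=ddiff(ee),
        dd_sp=ddiff(sp),
        d_s=d_s,
        d_ssum=d_ssum,
        sas_mt=sas_mt,
        snsas_mt=sn / sas_mt if sas_mt > 0 else 0.0,
        d_hydr=ff.hydrophobicity_delta(mutation.wt_aa, mutation.mt_aa),
    )


def _evaluate(features: FeatureVector, ws: WeightSet) -> Tuple[float, Dict[str, float]]:
    fdict = features.as_dict()
    contributions = {"intercept": ws.intercept}
    total = ws.intercept
    for term, w in ws.weights.items():
        if term not in fdict:
            raise KeyError(f"weight set has unknown term {term!r}")
        contributions[term] = w * fdict[term]
        total += contributions[term]
    return total, contributions


def predict_ddg(
    features: FeatureVector,
    flags: FlagProbabilities,
    weight_sets: Dict[str, WeightSet] | None = None,
) -> Tuple[float, Dict]:
    """Regime-selected ddG prediction (kcal/mol) plus a term-by-term report."""
    weight_sets = weight_sets or load_weight_sets()
    regime = flags.regime
    if regime not in weight_sets:
        raise KeyError(f"no weight set for regime {regime!r}")
    ws = weight_sets[regime]
    ddg, contributions = _evaluate(features, ws)
    report = {
        "ddg_pred": ddg,
        "regime": regime,
        "combined_probability": flags.combined,
        "flags": {
            "p_wt": flags.p_wt,
            "p_mt": flags.p_mt,
            "p_loc": flags.p_loc,
            "p_sse": flags.p_sse,
        },
        "features": features.as_dict(),
        "contributions": contributions,
        "weights_provenance": ws.provenance,
    }
    return ddg, report


def predict_ddg_noflags(
    features: FeatureVector,
    weight_sets: Dict[str, WeightSet] | None = None,
) -> Tuple[float, Dict]:
    """Single-equation prediction with the pooled "all" weight set."""
    weight_sets = weight_sets or load_weight_sets()
    ws = weight_sets["all"]
    ddg, contributions = _evaluate(features, ws)
    report = {
        "ddg_pred": ddg,
        "regime": "all",
        "features": features.as_dict(),
        "contributions": contributions,
        "weights_provenance": ws.provenance,
    }
    return ddg, report
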