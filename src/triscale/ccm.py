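"""Curated central-carbon-metabolism (CCM) network.

An integrated model of mammalian central carbon metabolism — glycolysis,
TCA cycle, pentose phosphate pathway and fatty-acid synthesis/consumption —
coupled to the growth-factor/PI3K/AKT/mTOR, RAS/ERK, JAK/STAT, NF-κB,
HIF-1α/PHD and p53/MDM2 signaling axes and to the enzyme genes they
regulate.  Dimensions: 37 genes, 29 signaling species, 41 metabolites and
27 external inputs.

The wiring follows the KEGG pathway maps and the cancer-metabolism
literature (Warburg effect); kinetic and binding constants are a curated,
versioned parameter set in normalized (0, 1) units, tuned so that the
model reproduces the qualitative behaviour of the pathway (see the methods
note).  They are a faithful reconstruction, not measured values.

Exports the builder :func:`build_ccm_network`, the canonical Warburg
knockout set and named nominal external-input environments.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np

from .network import (
    GeneRule,
    InteractionRule,
    NetworkSpec,
    ReactionRule,
    validate_network,
)

__all__ = [
    "GENES",
    "SIGNALS",
    "METABOLITES",
    "INPUTS",
    "build_ccm_network",
    "ccm_network_path",
    "warburg_knockout_reactions",
    "nominal_inputs",
    "WARBURG_KNOCKOUT_ENZYMES",
]

GENES = [
    "glut1", "hk", "gpi", "pfk1", "pfk2", "fbp1", "aldo", "tpi", "gapdh",
    "pgk", "pgam", "eno", "pk", "ldh", "pdh", "pc", "cs", "acon", "idh",
    "ogdh", "scs", "sdh", "fh", "mdh", "pepck1", "g6pase", "g6pd", "pgd",
    "rpi", "rpe", "tkt", "tal", "acly", "acc", "fas", "acsl", "atp5",
]

SIGNALS = [
    "egfr", "igf1r", "irs1", "pi3k", "pdk1", "akt", "mtor", "s6k", "ras",
    "raf", "mek", "erk", "myc", "jak2", "stat3", "ikk", "nfkb", "hif1a",
    "phd", "vhl", "p53", "mdm2", "ampk", "lkb1", "pten", "gsk3b", "foxo",
    "srebp1", "pkc",
]

METABOLITES = [
    "glucose_ext", "glucose", "g6p", "f6p", "f16bp", "f26bp", "dhap",
    "ga3p", "bpg13", "pg3", "pg2", "pep", "pyruvate", "lactate",
    "acetyl_coa", "citrate", "isocitrate", "akg", "succinyl_coa",
    "succinate", "fumarate", "malate", "oaa", "pg6", "ru5p", "r5p", "x5p",
    "s7p", "e4p", "nadph", "nadp", "nadh", "nad", "atp", "adp", "ffa",
    "malonyl_coa", "acyl_coa", "co2", "ros", "amp",
]

INPUTS = [
    "glucose_supply", "oxygen", "insulin", "glucagon", "epinephrine",
    "egf", "igf1", "il6", "tnfa", "wnt", "tgfb", "glutamine",
    "amino_acids", "fatty_acids_ext", "serum", "hypoxia_mimetic",
    "genotoxic_stress", "oxidative_stress", "ph_ext", "osmotic_stress",
    "temperature", "growth_factor_misc", "ifng", "lactate_ext",
    "pyruvate_ext", "co2_ext", "matrix_stiffness",
]

DISPLAY_NAMES = {
    "hif1a": "HIF-1α",
    "nfkb": "NF-κB",
    "pi3k": "PI3K",
    "mtor": "mTOR",
    "p53": "p53",
    "phd": "PHD",
    "r5p": "ribose 5P",
    "g6p": "glucose 6P",
    "f6p": "fructose 6P",
    "f16bp": "fructose 1,6-bisphosphate",
    "f26bp": "fructose 2,6-bisphosphate",
    "ga3p": "glyceraldehyde 3P",
    "pep": "phosphoenolpyruvate",
    "oaa": "oxaloacetate",
    "ffa": "free fatty acids",
    "g6pd": "glucose-6-phosphate dehydrogenase",
    "gpi": "glucose-6-phosphate isomerase",
    "pgd": "phospho-gluco dehydrogenase",
    "rpi": "ribose 5P isomerase",
    "tkt": "transketolase",
    "tal": "transaldolase",
    "pk": "pyruvate kinase",
    "ldh": "lactate dehydrogenase",
    "hk": "hexokinase",
    "glut1": "glucose transporter 1",
    "pdh": "pyruvate dehydrogenase",
    "pc": "pyruvate carboxylase",
    "acsl": "acyl-CoA synthetase",
    "fas": "fatty acid synthase",
    "pepck1": "phosphoenolpyruvate carboxykinase 1",
    "scs": "succinyl-CoA synthetase",
}

# Enzymes knocked out (rate constant -> 0) to slow oxidative phosphorylation
# and induce the Warburg phenotype.
WARBURG_KNOCKOUT_ENZYMES = ["pdh", "pc", "acsl", "fas", "pepck1", "scs"]

_G = {name: i for i, name in enumerate(GENES)}
_S = {name: i for i, name in enumerate(SIGNALS)}
_Z = {name: i for i, name in enumerate(METABOLITES)}
_U = {name: i for i, name in enumerate(INPUTS)}


def _zmap(d: dict[str, float]) -> dict[int, float]:
    return {_Z[k]: v for k, v in d.items()}


def _umap(d: dict[str, float]) -> dict[int, float]:
    return {_U[k]: v for k, v in d.items()}


def _smap(d: dict[str, float]) -> dict[int, float]:
    return {_S[k]: v for k, v in d.items()}


def _gene(name, basal, decay, tf, act_met=None, act_inp=None,
          inh_met=None, inh_inp=None, inh_sig=None) -> GeneRule:
    return GeneRule(
        gene_index=_G[name],
        basal_rate=basal,
        decay_rate=decay,
        tf_activators=_smap(tf),
        act_met=_zmap(act_met or {}),
        act_inp=_umap(act_inp or {}),
        inh_met=_zmap(inh_met or {}),
        inh_inp=_umap(inh_inp or {}),
        inh_sig=_smap(inh_sig or {}),
    )


def _gene_rules() -> list[GeneRule]:
    """One transcription rule per enzyme gene.

    Glycolytic genes sit under HIF-1α and/or MYC; pentose-phosphate genes
    under MYC (several repressed by p53); gluconeogenic genes under FOXO
    with insulin/AKT repression; lipogenic genes under SREBP-1.  Basal and
    decay rates are balanced so that, at nominal signaling tone, the genes
    hold their level and drift upward only when their transcription
    factors are over-expressed.
    """
    return [
        _gene("glut1", 0.05, 0.181, {"hif1a": 0.9, "myc": 0.9}, inh_sig={"p53": 0.8}),
        _gene("hk", 0.05, 0.233, {"hif1a": 0.9, "myc": 0.9}),
        _gene("gpi", 0.05, 0.365, {"hif1a": 0.8}),
        _gene("pfk1", 0.05, 0.385, {"hif1a": 0.85}),
        _gene("pfk2", 0.05, 0.423, {"hif1a": 0.8}, act_inp={"insulin": 0.3}),
        _gene("fbp1", 0.05, 0.167, {"foxo": 0.75}, inh_inp={"insulin": 0.5}, inh_sig={"akt": 0.6}),
        _gene("aldo", 0.05, 0.365, {"hif1a": 0.8}),
        _gene("tpi", 0.05, 0.48, {"myc": 0.75}),
        _gene("gapdh", 0.05, 0.365, {"hif1a": 0.8}),
        _gene("pgk", 0.05, 0.357, {"hif1a": 0.78}),
        _gene("pgam", 0.05, 0.463, {"myc": 0.72}),
        _gene("eno", 0.05, 0.345, {"hif1a": 0.75}),
        _gene("pk", 0.05, 0.233, {"hif1a": 0.9, "myc": 0.9}),
        _gene("ldh", 0.05, 0.232, {"hif1a": 0.85, "myc": 0.95}),
        _gene("pdh", 0.05, 0.214, {"foxo": 0.72}, inh_sig={"hif1a": 0.7}),
        _gene("pc", 0.05, 0.263, {"foxo": 0.68}),
        _gene("cs", 0.05, 0.439, {"myc": 0.68}),
        _gene("acon", 0.05, 0.256, {"foxo": 0.66}),
        _gene("idh", 0.05, 0.256, {"foxo": 0.66}),
        _gene("ogdh", 0.05, 0.256, {"foxo": 0.66}),
        _gene("scs", 0.05, 0.256, {"foxo": 0.66}),
        _gene("sdh", 0.05, 0.256, {"foxo": 0.66}),
        _gene("fh", 0.05, 0.256, {"foxo": 0.66}),
        _gene("mdh", 0.05, 0.439, {"myc": 0.68}),
        _gene("pepck1", 0.05, 0.167, {"foxo": 0.75}, inh_inp={"insulin": 0.5}, inh_sig={"akt": 0.6}),
        _gene("g6pase", 0.05, 0.169, {"foxo": 0.78}, inh_inp={"insulin": 0.5}, inh_sig={"akt": 0.65}),
        _gene("g6pd", 0.05, 0.408, {"myc": 0.8}, inh_sig={"p53": 0.7}),
        _gene("pgd", 0.05, 0.48, {"myc": 0.75}),
        _gene("rpi", 0.05, 0.486, {"myc": 0.76}),
        _gene("rpe", 0.05, 0.463, {"myc": 0.72}),
        _gene("tkt", 0.05, 0.497, {"myc": 0.78}),
        _gene("tal", 0.05, 0.474, {"myc": 0.74}),
        _gene("acly", 0.05, 0.435, {"srebp1": 0.72}),
        _gene("acc", 0.05, 0.435, {"srebp1": 0.72}),
        _gene("fas", 0.05, 0.46, {"srebp1": 0.78}),
        _gene("acsl", 0.05, 0.42, {"srebp1": 0.7}),
        _gene("atp5", 0.05, 0.451, {"myc": 0.7}),
    ]


def _interaction_rules() -> list[InteractionRule]:
    """Signaling wiring: one production interaction per route plus a
    first-order degradation interaction per species."""
    rules: list[InteractionRule] = []

    def prod(target, activators=None, basal=1.0, enh_met=None, enh_inp=None,
             inh_met=None, inh_inp=None, inh_sig=None):
        rules.append(InteractionRule(
            interaction_index=len(rules),
            target=_S[target],
            activators=_smap(activators or {}),
            basal=basal,
            enh_met=_zmap(enh_met or {}),
            enh_inp=_umap(enh_inp or {}),
            inh_met=_zmap(inh_met or {}),
            inh_inp=_umap(inh_inp or {}),
            inh_sig=_smap(inh_sig or {}),
        ))

    # receptors / sources
    prod("egfr", basal=0.35, enh_inp={"egf": 0.8, "serum": 0.4})
    prod("igf1r", basal=0.35, enh_inp={"igf1": 0.8, "insulin": 0.5})
    prod("jak2", basal=0.3, enh_inp={"il6": 0.8, "ifng": 0.3})
    prod("ikk", basal=0.28, enh_inp={"tnfa": 0.8})
    prod("lkb1", basal=0.3)
    prod("vhl", basal=0.25)
    prod("pten", basal=0.3, inh_sig={"nfkb": 0.4})
    prod("gsk3b", basal=0.35, inh_sig={"akt": 0.7})
    prod("foxo", basal=0.38, inh_sig={"akt": 0.75})
    prod("pkc", basal=0.25, enh_inp={"fatty_acids_ext": 0.4})
    prod("phd", basal=0.4, enh_inp={"oxygen": 0.85}, inh_met={"succinate": 0.5},
         inh_inp={"hypoxia_mimetic": 0.8})
    # PI3K/AKT/mTOR axis
    prod("irs1", activators={"igf1r": 0.75}, enh_inp={"insulin": 0.6}, inh_sig={"s6k": 0.5})
    prod("pi3k", activators={"irs1": 0.55}, inh_sig={"pten": 0.7})
    prod("pi3k", activators={"egfr": 0.35}, inh_sig={"pten": 0.7})
    prod("pdk1", activators={"pi3k": 0.8})
    prod("akt", activators={"pdk1": 0.8}, inh_sig={"pten": 0.35})
    prod("mtor", activators={"akt": 0.8}, enh_inp={"amino_acids": 0.5}, inh_sig={"ampk": 0.6})
    prod("s6k", activators={"mtor": 0.7})
    prod("srebp1", activators={"mtor": 0.7}, enh_inp={"insulin": 0.4})
    # RAS/ERK axis
    prod("ras", activators={"egfr": 0.65}, enh_inp={"egf": 0.4})
    prod("raf", activators={"ras": 0.8})
    prod("mek", activators={"raf": 0.8})
    prod("erk", activators={"mek": 0.85})
    prod("myc", activators={"erk": 0.6}, inh_sig={"gsk3b": 0.55})
    prod("myc", activators={"stat3": 0.5})
    # JAK/STAT and NF-kB
    prod("stat3", activators={"jak2": 0.75})
    prod("nfkb", activators={"ikk": 0.75})
    # hypoxia axis
    prod("hif1a", basal=0.34, inh_sig={"phd": 0.85, "vhl": 0.5},
         enh_inp={"hypoxia_mimetic": 0.7})
    prod("hif1a", activators={"mtor": 0.3})
    # p53 / MDM2
    prod("p53", basal=0.3, enh_inp={"genotoxic_stress": 0.6}, enh_met={"ros": 0.85},
         inh_sig={"mdm2": 0.8}, inh_met={"nadph": 0.75})
    prod("mdm2", activators={"akt": 0.55})
    prod("mdm2", activators={"p53": 0.3})
    # energy stress
    prod("ampk", activators={"lkb1": 0.65}, enh_met={"amp": 0.6}, inh_met={"atp": 0.5})

    for name in SIGNALS:
        j = _S[name]
        rules.append(InteractionRule(
            interaction_index=len(rules),
            target=None,
            activators={j: 0.85},
            consumed=(j,),
        ))
    return rules


def _reaction_rules() -> list[ReactionRule]:
    """Metabolic reactions: glycolysis (with gluconeogenic branches), TCA
    cycle, pentose phosphate pathway, fatty-acid metabolism, oxidative
    phosphorylation and lumped housekeeping fluxes (ATP demand, NADPH-
    dependent ROS clearance, lactate/CO2 efflux, nucleotide synthesis)."""
    rules: list[ReactionRule] = []

    def rxn(gene, substrates, products, K, K_M, enh_met=None, enh_inp=None,
            inh_met=None, inh_inp=None):
        rules.append(ReactionRule(
            reaction_index=len(rules),
            substrates=tuple(_Z[s] for s in substrates),
            products=tuple(_Z[s] for s in products),
            catalyzing_gene=_G[gene],
            rate_constant=K,
            michaelis_constant=K_M,
            enh_met=_zmap(enh_met or {}),
            enh_inp=_umap(enh_inp or {}),
            inh_met=_zmap(inh_met or {}),
            inh_inp=_umap(inh_inp or {}),
        ))

    # glucose supply and glycolysis
    rxn("glut1", [], ["glucose_ext"], 0.2, 0.4, enh_inp={"glucose_supply": 0.9})
    rxn("glut1", ["glucose_ext"], ["glucose"], 0.6, 0.3)
    rxn("hk", ["glucose"], ["g6p"], 0.7, 0.25)
    rxn("gpi", ["g6p"], ["f6p"], 0.35, 0.3, enh_met={"adp": 0.9}, inh_met={"atp": 0.5})
    rxn("pfk1", ["f6p"], ["f16bp"], 0.5, 0.3, enh_met={"f26bp": 0.8})
    rxn("pfk2", ["f6p"], ["f26bp"], 0.2, 0.35, enh_inp={"insulin": 0.4})
    rxn("fbp1", ["f16bp"], ["f6p"], 0.25, 0.35, inh_met={"f26bp": 0.7})
    rxn("fbp1", ["f26bp"], ["f6p"], 0.3, 0.35)
    rxn("aldo", ["f16bp"], ["dhap", "ga3p"], 0.45, 0.3)
    rxn("tpi", ["dhap"], ["ga3p"], 0.6, 0.3)
    rxn("gapdh", ["ga3p", "nad"], ["bpg13", "nadh"], 0.75, 0.2)
    rxn("pgk", ["bpg13", "adp"], ["pg3", "atp"], 0.3, 0.25)
    rxn("pgam", ["pg3"], ["pg2"], 0.5, 0.3)
    rxn("eno", ["pg2"], ["pep"], 0.5, 0.3)
    rxn("pk", ["pep", "adp"], ["pyruvate", "atp"], 0.45, 0.3, enh_met={"f16bp": 0.8})
    rxn("ldh", ["pyruvate", "nadh"], ["lactate", "nad"], 0.8, 0.1)
    # pyruvate branch point and TCA cycle
    rxn("pdh", ["pyruvate", "nad"], ["acetyl_coa", "nadh", "co2"], 0.6, 0.2)
    rxn("pc", ["pyruvate", "atp"], ["oaa", "adp"], 0.3, 0.35)
    rxn("cs", ["acetyl_coa", "oaa"], ["citrate"], 0.6, 0.25)
    rxn("acon", ["citrate"], ["isocitrate"], 0.4, 0.3)
    rxn("idh", ["isocitrate", "nad"], ["akg", "nadh", "co2"], 0.55, 0.3)
    rxn("ogdh", ["akg", "nad"], ["succinyl_coa", "nadh", "co2"], 0.55, 0.3)
    rxn("scs", ["succinyl_coa", "adp"], ["succinate", "atp"], 0.55, 0.3)
    rxn("sdh", ["succinate", "nad"], ["fumarate", "nadh"], 0.5, 0.3)
    rxn("fh", ["fumarate"], ["malate"], 0.55, 0.3)
    rxn("mdh", ["malate", "nad"], ["oaa", "nadh"], 0.5, 0.3)
    # gluconeogenic branches
    rxn("pepck1", ["oaa"], ["pep", "co2"], 0.25, 0.35, enh_met={"atp": 0.9})
    rxn("g6pase", ["g6p"], ["glucose_ext"], 0.12, 0.35, enh_met={"atp": 0.9})
    # pentose phosphate pathway
    rxn("g6pd", ["g6p", "nadp"], ["pg6", "nadph"], 0.6, 0.3, enh_met={"atp": 0.9}, inh_met={"adp": 0.9})
    rxn("pgd", ["pg6", "nadp"], ["ru5p", "nadph", "co2"], 0.6, 0.3)
    rxn("rpi", ["ru5p"], ["r5p"], 0.45, 0.3)
    rxn("rpe", ["x5p"], ["ru5p"], 0.5, 0.3)
    rxn("tkt", ["f6p", "ga3p"], ["x5p", "e4p"], 0.45, 0.3)
    rxn("tkt", ["r5p", "x5p"], ["s7p", "ga3p"], 0.12, 0.4)
    rxn("tal", ["s7p", "ga3p"], ["f6p", "e4p"], 0.4, 0.3)
    # fatty-acid metabolism
    rxn("acly", ["citrate"], ["acetyl_coa", "oaa"], 0.25, 0.3)
    rxn("acc", ["acetyl_coa"], ["malonyl_coa"], 0.4, 0.3)
    rxn("fas", ["malonyl_coa", "nadph"], ["ffa", "nadp"], 0.4, 0.3)
    rxn("acsl", ["ffa"], ["acyl_coa"], 0.3, 0.3)
    rxn("acsl", ["acyl_coa", "nad"], ["acetyl_coa", "nadh"], 0.3, 0.35)
    # oxidative phosphorylation and energy turnover
    rxn("atp5", ["nadh", "adp"], ["nad", "atp"], 0.85, 0.35, enh_inp={"oxygen": 0.9})
    rxn("atp5", [], ["ros"], 0.08, 0.5, enh_met={"pyruvate": 0.9},
        enh_inp={"oxidative_stress": 0.6})
    rxn("atp5", ["atp"], ["adp"], 1.0, 0.35)
    rxn("atp5", ["nadh"], ["nad"], 0.1, 0.3, enh_inp={"oxygen": 0.5})
    rxn("idh", ["nad"], ["nadh"], 0.1, 0.4)
    rxn("pgd", ["nadph"], ["nadp"], 0.08, 0.4)
    # housekeeping / lumped fluxes
    rxn("g6pd", ["ros", "nadph"], ["nadp"], 0.45, 0.25)
    rxn("glut1", ["lactate"], [], 0.35, 0.4)
    rxn("idh", ["r5p"], ["amp"], 0.3, 0.2)
    rxn("atp5", ["amp"], [], 0.35, 0.3)
    rxn("atp5", ["co2"], [], 0.5, 0.3)
    rxn("tal", ["e4p"], [], 0.35, 0.4)
    # lumped NADPH-consuming biosynthesis/antioxidant regeneration
    rxn("acon", ["nadph"], ["nadp"], 0.4, 0.3)
    return rules


# Calibrated kinetic parameter set (versioned): rate constants,
# Michaelis constants and reaction-modifier strengths found by the
# checklist-driven hill climb in `triscale.plant.tune_parameters`
# (calibration seeds 20250919/11/12), flat in compiled layout order.
TUNED_PARAMETERS = {
    "rate_constants": np.array([0.258573, 0.490289, 0.87719, 0.397399, 0.650572, 0.17905, 0.556386, 0.449631, 0.39478, 0.555516, 0.863157, 0.420142, 0.53939, 0.594193, 0.637591, 0.697422, 0.667699, 0.417935, 0.933954, 0.077904, 0.975063, 0.420303, 0.451249, 0.639265, 0.574436, 0.513235, 0.099553, 0.065703, 0.466425, 0.573063, 0.380618, 0.42219, 0.17219, 0.242575, 0.31929, 0.027589, 0.523398, 0.310823, 0.149028, 0.305285, 1, 0.138725, 0.939756, 0.068246, 0.233065, 0.038088, 0.575, 0.196213, 0.354879, 0.1831, 0.398188, 0.34509, 0.4]),
    "michaelis_constants": np.array([0.470308, 0.375133, 0.274585, 0.443027, 0.495427, 0.132692, 0.091062, 0.596891, 0.232673, 0.195179, 0.109768, 0.126949, 0.572253, 0.355499, 0.198673, 0.282092, 0.221556, 0.325646, 0.138973, 0.428165, 0.187, 0.05, 0.332167, 0.359173, 0.095594, 0.708232, 0.243451, 0.169213, 0.12769, 0.284896, 0.519924, 0.108792, 0.210891, 0.377683, 0.507064, 0.177504, 0.214906, 0.51204, 0.300576, 0.081074, 0.28556, 0.55163, 0.05, 0.261693, 0.160643, 0.27237, 0.05, 0.552461, 0.28802, 0.436362, 0.202838, 0.500775, 0.3]),
    "reaction_enh": np.array([0.77684, 0, 0, 0.858301, 0.930994, 0.483411, 0, 0, 0, 0, 0, 0, 0, 0, 0.768178, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.881482, 0.873262, 0.565954, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.927371, 0.95, 0.814333, 0, 0.641356, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
    "reaction_inh": np.array([0, 0, 0, 0.555419, 0, 0, 0.707078, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.692591, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
}


def build_ccm_network(tuned: bool = True) -> NetworkSpec:
    """Construct and validate the curated CCM :class:`NetworkSpec`.

    With ``tuned=True`` (default) the calibrated kinetic parameter set is
    applied on top of the structural wiring; ``tuned=False`` returns the
    raw hand-curated constants (the calibration starting point).
    """
    spec = NetworkSpec(
        gene_names=list(GENES),
        signaling_names=list(SIGNALS),
        metabolite_names=list(METABOLITES),
        input_names=list(INPUTS),
        gene_rules=_gene_rules(),
        interaction_rules=_interaction_rules(),
        reaction_rules=_reaction_rules(),
        display_names=dict(DISPLAY_NAMES),
    )
    if tuned:
        from .plant import spec_with_parameter_table

        spec = spec_with_parameter_table(spec, TUNED_PARAMETERS)
    return validate_network(spec)


def ccm_network_path() -> Path:
    """Path of the packaged ``ccm.net.yaml`` file."""
    return Path(importlib.resources.files("triscale").joinpath("data/ccm.net.yaml"))


def warburg_knockout_reactions(spec: NetworkSpec) -> list[int]:
    """Reaction indices catalyzed by the six Warburg knockout enzymes."""
    genes = {spec.gene_index(g) for g in WARBURG_KNOCKOUT_ENZYMES}
    return [r.reaction_index for r in spec.reaction_rules if r.catalyzing_gene in genes]


def nominal_inputs(spec: NetworkSpec, scenario: str = "normal") -> np.ndarray:
    """Named external-input environments.

    ``normal`` is a fed, normoxic, growth-factor-stimulated condition;
    ``hypoxia`` lowers oxygen; ``insulin_deprivation`` removes insulin and
    IGF-1 tone.
    """
    u = np.full(spec.c, 0.2)

    def set_(name, val):
        u[spec.input_index(name)] = val

    set_("glucose_supply", 0.8)
    set_("oxygen", 0.9)
    set_("insulin", 0.6)
    set_("egf", 0.5)
    set_("igf1", 0.5)
    set_("serum", 0.5)
    set_("il6", 0.3)
    set_("tnfa", 0.25)
    set_("amino_acids", 0.6)
    set_("glutamine", 0.5)
    set_("genotoxic_stress", 0.1)
    set_("hypoxia_mimetic", 0.05)
    if scenario == "normal":
        pass
    elif scenario == "hypoxia":
        set_("oxygen", 0.1)
        set_("hypoxia_mimetic", 0.7)
    elif scenario == "insulin_deprivation":
        set_("insulin", 0.02)
        set_("igf1", 0.05)
    else:
        raise KeyError(f"unknown input environment {scenario!r}")
    return u
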