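"""The FcεRI interaction library as executable data.

The library collects the molecular interactions of early high-affinity IgE
receptor signaling in mast cells as site-graph rewrite rules, organized into
composable sub-libraries:

``ligand_receptor``
    Bivalent antigen (DNP--BSA with two hapten groups that flip between
    inaccessible and accessible states) binding and crosslinking bivalent
    cell-surface IgE-receptor complexes.  Cyclic aggregates never form
    because binding rules are strictly bimolecular.
``proximal``
    Constitutive Lyn/Fyn association with the receptor, trans-phosphorylation
    of receptor tyrosines across a ligand bridge, SH2-mediated kinase
    recruitment with enhanced activity, Syk recruitment to the phosphorylated
    γ-ITAM and Syk trans-autophosphorylation of the activation loop.
``pag1_csk``
    Negative regulation of the Src-family kinases: Pag1 binding and
    phosphorylation, Csk recruitment, cis phosphorylation of the SFK
    C-terminal inhibitory tyrosine, and SH2-mediated autoinhibitory closure.
``lat_downstream``
    The numbered rules 1--48: Syk-catalyzed Lat phosphorylation, adaptor
    recruitment (Grb2/Grap2/Lcp2/Gab2), Plcg1/Plcg2, PI3K, Btk, and Inpp5d
    binding and catalysis.
``lipid_background``
    The numbered rules 49--51 (Pten and PIP2/PI4P interconversion) plus two
    auxiliary turnover reactions (first-order IP3 degradation and DAG
    recycling to PI4P) that close the lipid cycle so that second-messenger
    outputs admit steady states.
``implicit_phosphatase``
    One first-order dephosphorylation rule per phosphosite, acting on unbound
    phosphosites, with a single shared rate constant.
``gab2_feedback``
    Rule 15 (Gab2 PH--PIP3 binding) together with the two membrane
    companions that make the recruitment productive under well-mixed mass
    action: Fyn phosphorylation of PIP3-tethered Gab2, and PIP2 capture by
    PI3K held at the membrane through PIP3-tethered Gab2.
``input_signal``
    The reduced-model input: an adjustable signal activates Syk and Fyn
    (first order in the inactive kinase, realized by tethering the kinase to
    a membrane anchor and, for Syk, setting its activation loop), and each
    active kinase decays through a first-order deactivation.

Amounts are copy numbers per cell in well-mixed implicit compartments
(cytosol, plasma membrane, extracellular fluid); bimolecular rate constants
are per copy number per second.  Numeric parameter defaults are documented
placeholders in physiological ranges -- see ``docs/methods.md``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import pandas as pd

from .model import Model, Observable, ParameterSet, parse_molecule_type, parse_rule_line
from .rules import Rule
from .sitegraph import parse_complex

__all__ = [
    "MOLECULE_TYPES",
    "NUMBERED_RULE_TEXT",
    "LibraryEntry",
    "library_index",
    "list_rules",
    "default_parameters",
    "default_seed_amounts",
    "ModelSelection",
    "build_model",
    "ffl_model",
    "write_sublibrary_text",
]


# ---------------------------------------------------------------------------
# Molecule type table (UniProt names, rat residue numbering)
# ---------------------------------------------------------------------------

_MOLECULE_TYPE_TEXT = [
    # ligand & receptor: DNP-BSA with two hapten sites (inaccessible 'i' /
    # accessible 'a'); Rec is the IgE-receptor unit with two antigen-combining
    # sites f1/f2, the Lyn/Fyn unique-domain site u, the beta-ITAM N-terminal
    # tyrosine b_Y210, the non-canonical beta tyrosine b_Y224, and the
    # gamma-ITAM (both canonical tyrosines treated as one site) g
    "Lig(d1~i~a,d2~i~a)",
    "Rec(f1,f2,u,b_Y210~0~P,b_Y224~0~P,g~0~P)",
    "Lyn(U,SH2,SH3,PTK,Yc~0~P)",
    "Fyn(U,SH2,SH3,PTK,Yc~0~P)",
    "Syk(tSH2,PTK,Y519_Y520~0~P)",
    "Csk(SH2,PTK)",
    "Pag1(sfk,y317~0~P)",
    "Lat(Y136~0~P,Y175~0~P)",
    "Grb2(SH2,cSH3)",
    "Grap2(SH2,SH3)",
    "Lcp2(RxxK,PRS)",
    "Plcg1(SH2,SH3,PLC,Y783~0~P)",
    "Plcg2(SH2,PLC,Y753~0~P)",
    "Gab2(PRS,PH,Y441~0~P)",
    "Pi3k(p85_SH2,PI3Kc)",
    "Btk(PH,PTK)",
    "Inpp5d(SH2,C2,IPP)",
    "PI45P2(headgroup)",
    "PI345P3(headgroup)",
    "PI34P2(headgroup)",
    "PI4P(headgroup)",
    "IP3()",
    "DAG()",
    # reduced-model membrane anchor for input-activated kinases
    "Anchor(a)",
]

MOLECULE_TYPES = {
    t.name: t for t in (parse_molecule_type(s) for s in _MOLECULE_TYPE_TEXT)
}


# ---------------------------------------------------------------------------
# The numbered rules (1-51), whitespace-normalized
# ---------------------------------------------------------------------------

_S_LAT = "Phosphorylation of Lat"
_S_PARTNERS = "Interactions among Lat and its binding partners"
_S_PI3K_REC = "Recruitment of PI3K to Gab2"
_S_PI3K_ACT = "PI3K activity"
_S_BTK = "Btk-mediated activation of Plcg1"
_S_PLCG1 = "Plcg1 activity"
_S_PLCG2 = "Recruitment and activity of Plcg2"
_S_SHIP_REC = "Activation of Inpp5d"
_S_SHIP_ACT = "Inpp5d activity"
_S_LIPID = "Additional lipid reactions"

#: (number, section, rule text, signed influence edges (src, dst, sign))
NUMBERED_RULE_TEXT = [
    (1, _S_LAT, "Syk(tSH2!+,PTK) + Lat(Y136~0) -> Syk(tSH2!+,PTK!1).Lat(Y136~0!1) kfSykLat", []),
    (2, _S_LAT, "Syk(PTK!1).Lat(Y136~0!1) -> Syk(PTK) + Lat(Y136~0) krSykLat", []),
    (3, _S_LAT, "Syk(PTK!1,Y519_Y520~P).Lat(Y136~0!1) -> Syk(PTK,Y519_Y520~P) + Lat(Y136~P) kpSykLat136_1", [("Syk", "Lat", 1)]),
    (4, _S_LAT, "Syk(PTK!1,Y519_Y520~0).Lat(Y136~0!1) -> Syk(PTK,Y519_Y520~0) + Lat(Y136~P) kpSykLat136_2", [("Syk", "Lat", 1)]),
    (5, _S_LAT, "Syk(tSH2!+,PTK) + Lat(Y175~0) -> Syk(tSH2!+,PTK!1).Lat(Y175~0!1) kfSykLat", []),
    (6, _S_LAT, "Syk(PTK!1).Lat(Y175~0!1) -> Syk(PTK) + Lat(Y175~0) krSykLat", []),
    (7, _S_LAT, "Syk(PTK!1,Y519_Y520~P).Lat(Y175~0!1) -> Syk(PTK,Y519_Y520~P) + Lat(Y175~P) kpSykLat175_2", [("Syk", "Lat", 1)]),
    (8, _S_LAT, "Syk(PTK!1,Y519_Y520~0).Lat(Y175~0!1) -> Syk(PTK,Y519_Y520~0) + Lat(Y175~P) kpSykLat175_1", [("Syk", "Lat", 1)]),
    (9, _S_PARTNERS, "Lat(Y175~P) + Grb2(SH2) <-> Lat(Y175~P!1).Grb2(SH2!1) kfLatGrb2, krLatGrb2", [("Lat", "Grb2", 1)]),
    (10, _S_PARTNERS, "Lat(Y175~P) + Grap2(SH2) <-> Lat(Y175~P!1).Grap2(SH2!1) kfLatGrap2, krLatGrap2", [("Lat", "Grap2", 1)]),
    (11, _S_PARTNERS, "Grap2(SH3) + Lcp2(RxxK) <-> Grap2(SH3!1).Lcp2(RxxK!1) kfGrap2Lcp, krGrap2Lcp", [("Grap2", "Lcp2", 1)]),
    (12, _S_PARTNERS, "Lat(Y136~P) + Plcg1(SH2) <-> Lat(Y136~P!1).Plcg1(SH2!1) kfLatPlcg, krLatPlcg", [("Lat", "Plcg1", 1)]),
    (13, _S_PARTNERS, "Lcp2(PRS) + Plcg1(SH3) <-> Lcp2(PRS!1).Plcg1(SH3!1) kfLcp2Plcg1, krLcp2Plcg1", [("Lcp2", "Plcg1", 1)]),
    (14, _S_PARTNERS, "Grb2(cSH3) + Gab2(PRS) <-> Grb2(cSH3!1).Gab2(PRS!1) kfGrb2Gab2, krGrb2Gab2", [("Grb2", "Gab2", 1)]),
    (15, _S_PARTNERS, "PI345P3(headgroup) + Gab2(PH) <-> PI345P3(headgroup!1).Gab2(PH!1) kfGab2Pip3, krGab2Pip3", [("PIP3", "Gab2", 1)]),
    (16, _S_PI3K_REC, "Fyn(U!+,SH2,PTK) + Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~0) -> Fyn(U!+,SH2,PTK!3).Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~0!3) kfFynGab2", []),
    (17, _S_PI3K_REC, "Rec(b_Y210~P!4).Fyn(U,SH2!4,PTK) + Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~0) -> Rec(b_Y210~P!4).Fyn(U,SH2!4,PTK!3).Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~0!3) kfFynGab2", []),
    (18, _S_PI3K_REC, "Fyn(PTK!1).Gab2(Y441~0!1) -> Fyn(PTK) + Gab2(Y441~0) krFynGab2", []),
    (19, _S_PI3K_REC, "Fyn(PTK!1).Gab2(Y441~0!1) -> Fyn(PTK) + Gab2(Y441~P) kpFynGab2", [("Fyn", "Gab2", 1)]),
    (20, _S_PI3K_REC, "Gab2(Y441~P) + Pi3k(p85_SH2) <-> Gab2(Y441~P!1).Pi3k(p85_SH2!1) kfGab2Pi3k, krGab2Pi3k", [("Gab2", "PI3K", 1)]),
    (21, _S_PI3K_ACT, "Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~P!3).Pi3k(p85_SH2!3,PI3Kc) + PI45P2(headgroup) -> Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~P!3).Pi3k(p85_SH2!3,PI3Kc!4).PI45P2(headgroup!4) kfPi3kPip2", []),
    (22, _S_PI3K_ACT, "Pi3k(PI3Kc!1).PI45P2(headgroup!1) -> Pi3k(PI3Kc) + PI45P2(headgroup) krPi3kPip2", []),
    (23, _S_PI3K_ACT, "Pi3k(PI3Kc!1).PI45P2(headgroup!1) -> Pi3k(PI3Kc) + PI345P3(headgroup) kpPi3k DeleteMolecules", [("PI3K", "PIP3", 1)]),
    (24, _S_BTK, "Btk(PH) + PI345P3(headgroup) <-> Btk(PH!1).PI345P3(headgroup!1) kfBtkPip3, krBtkPip3", [("PIP3", "Btk", 1)]),
    (25, _S_BTK, "Btk(PH!+,PTK) + Plcg1(SH2!+,Y783~0) -> Btk(PH!+,PTK!1).Plcg1(SH2!+,Y783~0!1) kfBtkPlcg", []),
    (26, _S_BTK, "Btk(PTK!1).Plcg1(Y783~0!1) -> Btk(PTK) + Plcg1(Y783~0) krBtkPlcg", []),
    (27, _S_BTK, "Btk(PTK!1).Plcg1(Y783~0!1) -> Btk(PTK) + Plcg1(Y783~P) kpBtkPlcg", [("Btk", "Plcg1", 1)]),
    (28, _S_PLCG1, "Plcg1(SH2!+,PLC) + PI45P2(headgroup) -> Plcg1(SH2!+,PLC!1).PI45P2(headgroup!1) kfPlcgPip2", []),
    (29, _S_PLCG1, "Plcg1(PLC!1).PI45P2(headgroup!1) -> Plcg1(PLC) + PI45P2(headgroup) krPlcgPip2", []),
    (30, _S_PLCG1, "Plcg1(PLC!1,Y783~P).PI45P2(headgroup!1) -> Plcg1(PLC,Y783~P) + IP3() + DAG() kcPlcg DeleteMolecules", [("Plcg1", "IP3", 1)]),
    (31, _S_PLCG2, "Lat(Y136~P) + Plcg2(SH2) <-> Lat(Y136~P!1).Plcg2(SH2!1) kfLatPlcg, krLatPlcg", [("Lat", "Plcg2", 1)]),
    (32, _S_PLCG2, "Syk(tSH2!+,PTK) + Plcg2(SH2!+,Y753~0) -> Syk(tSH2!+,PTK!1).Plcg2(SH2!+,Y753~0!1) kfSykPlcg", []),
    (33, _S_PLCG2, "Syk(PTK!1).Plcg2(Y753~0!1) -> Syk(PTK) + Plcg2(Y753~0) krSykPlcg", []),
    (34, _S_PLCG2, "Syk(PTK!1).Plcg2(Y753~0!1) -> Syk(PTK) + Plcg2(Y753~P) kpSykPlcg", [("Syk", "Plcg2", 1)]),
    (35, _S_PLCG2, "Plcg2(SH2!+,PLC) + PI45P2(headgroup) -> Plcg2(SH2!+,PLC!1).PI45P2(headgroup!1) kfPlcgPip2", []),
    (36, _S_PLCG2, "Plcg2(PLC!1).PI45P2(headgroup!1) -> Plcg2(PLC) + PI45P2(headgroup) krPlcgPip2", []),
    (37, _S_PLCG2, "Plcg2(PLC!1,Y753~P).PI45P2(headgroup!1) -> Plcg2(PLC,Y753~P) + IP3() + DAG() kcPlcg DeleteMolecules", [("Plcg2", "IP3", 1)]),
    (38, _S_SHIP_REC, "Inpp5d(SH2,C2) + Rec(b_Y224~P) -> Inpp5d(SH2!1,C2).Rec(b_Y224~P!1) kfShipRec", [("Rec", "Inpp5d", 1)]),
    (39, _S_SHIP_REC, "Inpp5d(IPP,C2!+) + Rec(b_Y224~P) -> Inpp5d(IPP!1,C2!+).Rec(b_Y224~P!1) 100*kfShipRec", [("Rec", "Inpp5d", 1)]),
    (40, _S_SHIP_REC, "Inpp5d(SH2!1).Rec(b_Y224~P!1) -> Inpp5d(SH2) + Rec(b_Y224~P) krShipRec", []),
    (41, _S_SHIP_REC, "Inpp5d(SH2,C2) + PI34P2(headgroup) -> Inpp5d(SH2,C2!1).PI34P2(headgroup!1) kfShipPip2", [("PI34P2", "Inpp5d", 1)]),
    (42, _S_SHIP_REC, "Inpp5d(SH2!+,C2) + PI34P2(headgroup) -> Inpp5d(SH2!+,C2!1).PI34P2(headgroup!1) 100*kfShipPip2", [("PI34P2", "Inpp5d", 1)]),
    (43, _S_SHIP_REC, "Inpp5d(C2!1).PI34P2(headgroup!1) -> Inpp5d(C2) + PI34P2(headgroup) krShipPip2", []),
    (44, _S_SHIP_ACT, "Inpp5d(SH2!+,C2,IPP) + PI345P3(headgroup) -> Inpp5d(SH2!+,C2,IPP!1).PI345P3(headgroup!1) kfShipPip3", []),
    (45, _S_SHIP_ACT, "Inpp5d(SH2,C2!+,IPP) + PI345P3(headgroup) -> Inpp5d(SH2,C2!+,IPP!1).PI345P3(headgroup!1) kfShipPip3", []),
    (46, _S_SHIP_ACT, "Inpp5d(SH2!+,C2!+,IPP) + PI345P3(headgroup) -> Inpp5d(SH2!+,C2!+,IPP!1).PI345P3(headgroup!1) kfShipPip3", []),
    (47, _S_SHIP_ACT, "Inpp5d(IPP!1).PI345P3(headgroup!1) -> Inpp5d(IPP) + PI345P3(headgroup) krShipPip3", []),
    (48, _S_SHIP_ACT, "Inpp5d(IPP!1).PI345P3(headgroup!1) -> Inpp5d(IPP) + PI34P2(headgroup) kdpShipPip3 DeleteMolecules", [("Inpp5d", "PIP3", -1), ("Inpp5d", "PI34P2", 1)]),
    (49, _S_LIPID, "PI345P3(headgroup) -> PI45P2(headgroup) kPten DeleteMolecules", []),
    (50, _S_LIPID, "PI4P(headgroup) -> PI45P2(headgroup) kfP5 DeleteMolecules", []),
    (51, _S_LIPID, "PI45P2(headgroup) -> PI4P(headgroup) krP5 DeleteMolecules", []),
]


@dataclass
class LibraryEntry:
    """One annotated rule of the library."""

    name: str
    sublibrary: str
    text: str
    number: Optional[int] = None
    section: str = ""
    edges: list = field(default_factory=list)

    def parse(self) -> Rule:
        rule = parse_rule_line(self.text, name=self.name)
        rule.annotation = {
            "number": self.number,
            "sublibrary": self.sublibrary,
            "section": self.section,
            "edges": list(self.edges),
        }
        return rule


# ---------------------------------------------------------------------------
# Generated sub-libraries
# ---------------------------------------------------------------------------

def _ligand_receptor_entries() -> list:
    """Bivalent ligand / bivalent receptor scheme (effective ligand valence 2)."""
    entries = []
    for d in ("d1", "d2"):
        entries.append(LibraryEntry(
            f"lig_expose_{d}", "ligand_receptor",
            f"Lig({d}~i) <-> Lig({d}~a) kExpose, kHide",
            section="Ligand-receptor binding"))
    for d, other in (("d1", "d2"), ("d2", "d1")):
        for f in ("f1", "f2"):
            entries.append(LibraryEntry(
                f"lig_bind_{d}_{f}", "ligand_receptor",
                f"Lig({d}~a,{other}) + Rec({f}) -> Lig({d}~a!1,{other}).Rec({f}!1) kfLigRec",
                section="Ligand-receptor binding",
                edges=[("Lig", "Rec", 1)]))
            entries.append(LibraryEntry(
                f"lig_crosslink_{d}_{f}", "ligand_receptor",
                f"Lig({d}~a,{other}!+) + Rec({f}) -> Lig({d}~a!1,{other}!+).Rec({f}!1) kfLigRecX",
                section="Ligand-receptor binding",
                edges=[("Lig", "Rec", 1)]))
            entries.append(LibraryEntry(
                f"lig_unbind_{d}_{f}", "ligand_receptor",
                f"Lig({d}~a!1).Rec({f}!1) -> Lig({d}~a) + Rec({f}) krLigRec",
                section="Ligand-receptor binding"))
    return entries


_BRIDGES = [
    (fa, db, dc, fd)
    for fa in ("f1", "f2")
    for db, dc in (("d1", "d2"), ("d2", "d1"))
    for fd in ("f1", "f2")
]


def _proximal_entries() -> list:
    """Receptor/Lyn/Fyn/Syk module: trans phosphorylation across aggregates."""
    entries = []
    for kin in ("Lyn", "Fyn"):
        entries.append(LibraryEntry(
            f"{kin.lower()}_rec_unique", "proximal",
            f"{kin}(U) + Rec(u) <-> {kin}(U!1).Rec(u!1) kf{kin}Rec, kr{kin}Rec",
            section="Proximal signaling", edges=[("Rec", kin, 1)]))
        entries.append(LibraryEntry(
            f"{kin.lower()}_rec_sh2", "proximal",
            f"{kin}(SH2) + Rec(b_Y210~P) <-> {kin}(SH2!1).Rec(b_Y210~P!1) kf{kin}SH2, kr{kin}SH2",
            section="Proximal signaling", edges=[("Rec", kin, 1)]))
        # trans phosphorylation of receptor tyrosines in the same aggregate;
        # the anchored kinase reaches the partner receptor across the ligand
        for anchor, anchor_pat, rate_suffix in (
            ("u", "U!5).Rec(u!5", "Itam"),          # constitutive, via unique domain
            ("sh2", "SH2!5).Rec(b_Y210~P!5", "ItamStar"),  # recruited, enhanced
        ):
            for fa, db, dc, fd in _BRIDGES:
                for target in ("b_Y210", "b_Y224", "g"):
                    lhs = (f"{kin}({anchor_pat},{fa}!2).Lig({db}!2,{dc}!3)"
                           f".Rec({fd}!3,{target}~0)")
                    rhs = lhs.replace(f"{target}~0", f"{target}~P")
                    entries.append(LibraryEntry(
                        f"{kin.lower()}_trans_{anchor}_{fa}_{db}_{fd}_{target}",
                        "proximal",
                        f"{lhs} -> {rhs} kp{kin}{rate_suffix}",
                        section="Proximal signaling",
                        edges=[(kin, "Rec", 1)]))
    entries.append(LibraryEntry(
        "syk_rec", "proximal",
        "Syk(tSH2) + Rec(g~P) <-> Syk(tSH2!1).Rec(g~P!1) kfSykRec, krSykRec",
        section="Proximal signaling", edges=[("Rec", "Syk", 1)]))
    for loop_state, rate in (("P", "kpSykAuto1"), ("0", "kpSykAuto2")):
        for fa, db, dc, fd in _BRIDGES:
            lhs = (f"Syk(tSH2!5,Y519_Y520~{loop_state}).Rec(g~P!5,{fa}!2)"
                   f".Lig({db}!2,{dc}!3).Rec({fd}!3,g~P!4)"
                   f".Syk(tSH2!4,Y519_Y520~0)")
            rhs = (f"Syk(tSH2!5,Y519_Y520~{loop_state}).Rec(g~P!5,{fa}!2)"
                   f".Lig({db}!2,{dc}!3).Rec({fd}!3,g~P!4)"
                   f".Syk(tSH2!4,Y519_Y520~P)")
            entries.append(LibraryEntry(
                f"syk_auto_{loop_state}_{fa}_{db}_{fd}", "proximal",
                f"{lhs} -> {rhs} {rate}",
                section="Proximal signaling", edges=[("Syk", "Syk", 1)]))
    return entries


def _pag1_csk_entries() -> list:
    """Pag1/Csk negative regulation of the Src-family kinases."""
    entries = []
    for kin in ("Lyn", "Fyn"):
        k = kin.lower()
        entries.append(LibraryEntry(
            f"pag_bind_{k}", "pag1_csk",
            f"Pag1(sfk) + {kin}(SH3) <-> Pag1(sfk!1).{kin}(SH3!1) kfPagSfk, krPagSfk",
            section="Pag1/Csk regulation"))
        entries.append(LibraryEntry(
            f"pag_phos_{k}", "pag1_csk",
            f"Pag1(sfk!1,y317~0).{kin}(SH3!1) -> Pag1(sfk!1,y317~P).{kin}(SH3!1) kpPagSfk",
            section="Pag1/Csk regulation", edges=[(kin, "Pag1", 1)]))
        # Csk phosphorylates the SFK inhibitory C-terminal tyrosine in cis
        entries.append(LibraryEntry(
            f"csk_inhib_{k}", "pag1_csk",
            f"Pag1(sfk!1,y317~P!2).{kin}(SH3!1,Yc~0).Csk(SH2!2,PTK) -> "
            f"Pag1(sfk!1,y317~P!2).{kin}(SH3!1,Yc~P).Csk(SH2!2,PTK) kpCskSfk",
            section="Pag1/Csk regulation", edges=[("Csk", kin, -1)]))
        entries.append(LibraryEntry(
            f"sfk_close_{k}", "pag1_csk",
            f"{kin}(SH2,Yc~P) -> {kin}(SH2!1,Yc~P!1) kfSfkClose",
            section="Pag1/Csk regulation"))
        entries.append(LibraryEntry(
            f"sfk_open_{k}", "pag1_csk",
            f"{kin}(SH2!1,Yc~P!1) -> {kin}(SH2,Yc~P) krSfkOpen",
            section="Pag1/Csk regulation"))
    entries.append(LibraryEntry(
        "csk_pag", "pag1_csk",
        "Pag1(y317~P) + Csk(SH2) <-> Pag1(y317~P!1).Csk(SH2!1) kfPagCsk, krPagCsk",
        section="Pag1/Csk regulation", edges=[("Pag1", "Csk", 1)]))
    return entries


def _gab2_feedback_entries() -> list:
    """Rule 15 plus the membrane companions of the Gab2/PI3K positive loop."""
    entries = [
        e for e in _numbered_entries() if e.number == 15
    ]
    entries.append(LibraryEntry(
        "gab2_feedback_phos", "gab2_feedback",
        "Fyn(U!+,SH2,PTK) + Gab2(PH!+,Y441~0) -> Fyn(U!+,SH2,PTK!1).Gab2(PH!+,Y441~0!1) kfFynGab2",
        section=_S_PI3K_REC, edges=[("Fyn", "Gab2", 1)]))
    entries.append(LibraryEntry(
        "gab2_feedback_pi3k", "gab2_feedback",
        "Gab2(PH!+,Y441~P!1).Pi3k(p85_SH2!1,PI3Kc) + PI45P2(headgroup) -> "
        "Gab2(PH!+,Y441~P!1).Pi3k(p85_SH2!1,PI3Kc!2).PI45P2(headgroup!2) kfPi3kPip2",
        section=_S_PI3K_ACT, edges=[("PI3K", "PIP3", 1)]))
    return entries


def _lipid_background_entries() -> list:
    entries = [e for e in _numbered_entries() if e.number in (49, 50, 51)]
    entries.append(LibraryEntry(
        "ip3_degradation", "lipid_background",
        "IP3() -> 0 kdegIp3",
        section=_S_LIPID, edges=[]))
    entries.append(LibraryEntry(
        "dag_recycle", "lipid_background",
        "DAG() -> PI4P(headgroup) kRecycleDag",
        section=_S_LIPID, edges=[]))
    return entries


def phosphosites(type_names: Optional[Iterable] = None) -> list:
    """All (molecule, site) pairs carrying a 0/P phosphorylation state."""
    out = []
    for name, tdef in MOLECULE_TYPES.items():
        if type_names is not None and name not in type_names:
            continue
        for sdef in tdef.sites:
            if set(sdef.states) == {"0", "P"}:
                out.append((name, sdef.name))
    return out


def implicit_phosphatase_entries(
    type_names: Optional[Iterable] = None,
    exclude: Iterable = (),
    act_on_bound: bool = False,
) -> list:
    """First-order dephosphorylation of every phosphosite.

    By default a phosphosite is only dephosphorylated while unbound (binding
    shields it); set ``act_on_bound`` to relax that convention.
    """
    bond = "!?" if act_on_bound else ""
    entries = []
    excluded = set(exclude)
    for mol, site in phosphosites(type_names):
        if (mol, site) in excluded:
            continue
        entries.append(LibraryEntry(
            f"dephos_{mol}_{site}", "implicit_phosphatase",
            f"{mol}({site}~P{bond}) -> {mol}({site}~0{bond}) kDephos",
            section="Implicit phosphatases",
            edges=[]))
    return entries


def _input_signal_entries() -> list:
    """Signal-controlled Syk/Fyn activation for the reduced models.

    Activation is first order in the inactive kinase (rate constant
    ``signal``); it tethers the kinase to a membrane anchor (so rules that
    require receptor engagement, ``tSH2!+`` or ``U!+``, apply) and, for Syk,
    sets the activation loop.  Deactivation is first order per kinase and
    removes the anchor.
    """
    return [
        LibraryEntry(
            "syk_activation", "input_signal",
            "Syk(tSH2,Y519_Y520~0) -> Syk(tSH2!1,Y519_Y520~P).Anchor(a!1) signal",
            section="Input signal", edges=[]),
        LibraryEntry(
            "syk_deactivation", "input_signal",
            "Syk(tSH2!1,Y519_Y520~P).Anchor(a!1) -> Syk(tSH2,Y519_Y520~0) kdeactSyk DeleteMolecules",
            section="Input signal", edges=[]),
        LibraryEntry(
            "fyn_activation", "input_signal",
            "Fyn(U) -> Fyn(U!1).Anchor(a!1) signal",
            section="Input signal", edges=[]),
        LibraryEntry(
            "fyn_deactivation", "input_signal",
            "Fyn(U!1).Anchor(a!1) -> Fyn(U) kdeactFyn DeleteMolecules",
            section="Input signal", edges=[]),
    ]


def _btk_plcg2_entries() -> list:
    """Optional Btk action on Plcg2 (off by default)."""
    return [
        LibraryEntry(
            "btk_plcg2_bind", "btk_on_plcg2",
            "Btk(PH!+,PTK) + Plcg2(SH2!+,Y753~0) -> Btk(PH!+,PTK!1).Plcg2(SH2!+,Y753~0!1) kfBtkPlcg",
            section=_S_PLCG2),
        LibraryEntry(
            "btk_plcg2_unbind", "btk_on_plcg2",
            "Btk(PTK!1).Plcg2(Y753~0!1) -> Btk(PTK) + Plcg2(Y753~0) krBtkPlcg",
            section=_S_PLCG2),
        LibraryEntry(
            "btk_plcg2_phos", "btk_on_plcg2",
            "Btk(PTK!1).Plcg2(Y753~0!1) -> Btk(PTK) + Plcg2(Y753~P) kpBtkPlcg",
            section=_S_PLCG2, edges=[("Btk", "Plcg2", 1)]),
    ]


@lru_cache(maxsize=1)
def _numbered_entries() -> tuple:
    out = []
    for number, section, text, edges in NUMBERED_RULE_TEXT:
        sub = "lipid_background" if number >= 49 else "lat_downstream"
        out.append(LibraryEntry(
            f"rule_{number}", sub, text, number=number, section=section,
            edges=edges))
    return tuple(out)


#: Condensed influence edges at the granularity of the published motif map:
#: each summarizes a chain of library rules (named in the provenance field).
CONDENSED_EDGES = [
    ("Rec", "PIP3", 1, "rules 1-8, 9, 14, 16-23 (Syk/Lat/PI3K chain)"),
    ("Lat", "Btk", 1, "rules 9, 14, 16-24 (Grb2/Gab2/PI3K/PIP3 chain)"),
    ("Lat", "Lcp2", 1, "rules 10, 11 (Grap2 chain)"),
]


@lru_cache(maxsize=1)
def library_index() -> dict:
    """All sub-libraries as {name: [LibraryEntry, ...]}."""
    return {
        "ligand_receptor": _ligand_receptor_entries(),
        "proximal": _proximal_entries(),
        "pag1_csk": _pag1_csk_entries(),
        "lat_downstream": [e for e in _numbered_entries() if e.number <= 48],
        "lipid_background": _lipid_background_entries(),
        "implicit_phosphatase": implicit_phosphatase_entries(),
        "gab2_feedback": _gab2_feedback_entries(),
        "input_signal": _input_signal_entries(),
        "btk_on_plcg2": _btk_plcg2_entries(),
    }


def list_rules(filter: Optional[str] = None) -> pd.DataFrame:
    """Annotated rule table; filter by sub-library name or molecule name."""
    rows = []
    for sub, entries in library_index().items():
        for e in entries:
            rows.append({
                "number": e.number,
                "name": e.name,
                "sublibrary": sub,
                "section": e.section,
                "rule": e.text,
            })
    df = pd.DataFrame(rows, columns=["number", "name", "sublibrary", "section",
                                     "rule"])
    if filter:
        keys = [k.strip() for k in filter.split("+")]
        mask = df.sublibrary.isin(keys)
        for k in keys:
            if k in MOLECULE_TYPES:
                mask |= df.rule.str.contains(rf"\b{k}\(", regex=True)
        df = df[mask].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Default parameterization
# ---------------------------------------------------------------------------

#: Placeholder defaults (copy numbers, seconds).  Bimolecular constants are
#: per-copy-number per-second; see docs/methods.md for the rationale.
_DEFAULT_PARAMETERS = {
    # Syk-catalyzed Lat phosphorylation (rules 1-8); activation-loop
    # phosphorylation enhances Syk catalysis, hence the rate ordering
    "kfSykLat": 2e-5, "krSykLat": 1.0,
    "kpSykLat136_1": 10.0, "kpSykLat136_2": 0.5,
    "kpSykLat175_1": 0.5, "kpSykLat175_2": 10.0,
    # Lat partners (rules 9-15); the two Lat sites have different affinities,
    # and adaptor exchange on Lat is fast relative to phosphosite turnover
    "kfLatGrb2": 1e-5, "krLatGrb2": 0.5,
    "kfLatGrap2": 1e-5, "krLatGrap2": 0.5,
    "kfGrap2Lcp": 1e-6, "krGrap2Lcp": 0.01,
    "kfLatPlcg": 3e-6, "krLatPlcg": 0.05,
    "kfLcp2Plcg1": 1e-6, "krLcp2Plcg1": 0.1,
    "kfGrb2Gab2": 3e-6, "krGrb2Gab2": 1.0,
    "kfGab2Pip3": 2e-5, "krGab2Pip3": 0.2,
    # Fyn/Gab2/PI3K (rules 16-23)
    "kfFynGab2": 1e-5, "krFynGab2": 1.0, "kpFynGab2": 20.0,
    "kfGab2Pi3k": 1e-5, "krGab2Pi3k": 0.1,
    "kfPi3kPip2": 1e-5, "krPi3kPip2": 1.0, "kpPi3k": 10.0,
    # Btk/Plcg1 (rules 24-30)
    "kfBtkPip3": 3e-6, "krBtkPip3": 0.2,
    "kfBtkPlcg": 3e-6, "krBtkPlcg": 1.0, "kpBtkPlcg": 10.0,
    "kfPlcgPip2": 3e-6, "krPlcgPip2": 1.0, "kcPlcg": 10.0,
    # Plcg2 (rules 31-37)
    "kfSykPlcg": 1e-6, "krSykPlcg": 1.0, "kpSykPlcg": 10.0,
    # Inpp5d (rules 38-48); the 100x membrane enhancements are rule-level
    # multipliers on kfShipRec / kfShipPip2
    "kfShipRec": 1e-6, "krShipRec": 0.1,
    "kfShipPip2": 1e-6, "krShipPip2": 0.1,
    "kfShipPip3": 1e-6, "krShipPip3": 1.0, "kdpShipPip3": 10.0,
    # lipid background (rules 49-51 + turnover)
    "kPten": 0.05, "kfP5": 0.002, "krP5": 0.002,
    "kdegIp3": 0.02, "kRecycleDag": 0.02,
    # ligand-receptor module
    "kExpose": 1.0, "kHide": 1.0,
    "kfLigRec": 1e-6, "kfLigRecX": 1e-6, "krLigRec": 0.01,
    # proximal module
    "kfLynRec": 5e-5, "krLynRec": 20.0,
    "kfLynSH2": 5e-5, "krLynSH2": 0.12,
    "kfFynRec": 5e-5, "krFynRec": 20.0,
    "kfFynSH2": 5e-5, "krFynSH2": 0.12,
    "kpLynItam": 30.0, "kpLynItamStar": 100.0,
    "kpFynItam": 30.0, "kpFynItamStar": 100.0,
    "kfSykRec": 6e-5, "krSykRec": 0.13,
    "kpSykAuto1": 100.0, "kpSykAuto2": 1.0,
    # Pag1/Csk module
    "kfPagSfk": 1e-6, "krPagSfk": 0.1, "kpPagSfk": 10.0,
    "kfPagCsk": 1e-6, "krPagCsk": 0.1, "kpCskSfk": 10.0,
    "kfSfkClose": 10.0, "krSfkOpen": 0.1,
    # implicit phosphatases
    "kDephos": 0.2,
    # reduced-model input signal
    "signal": 0.0, "kdeactSyk": 0.1, "kdeactFyn": 0.1,
}


def default_parameters() -> ParameterSet:
    """Complete default ParameterSet for the whole library.

    Structural constraints from the interaction descriptions always hold:
    the membrane-enhanced Inpp5d binding steps are 100x their cytosolic
    counterparts (rule-level multipliers), and Syk activation-loop
    phosphorylation speeds up catalysis (``kpSykLat136_1 >= kpSykLat136_2``,
    ``kpSykLat175_2 >= kpSykLat175_1``).
    """
    p = ParameterSet()
    for k, v in _DEFAULT_PARAMETERS.items():
        p[k] = v
    assert p["kpSykLat136_1"] >= p["kpSykLat136_2"]
    assert p["kpSykLat175_2"] >= p["kpSykLat175_1"]
    return p


#: Default seed copy numbers per cell for the reduced Lat-branch models.
_DEFAULT_SEEDS = {
    "Syk": 3e4,
    "Fyn": 3e4,
    "Lat": 3e4,
    "Grb2": 5e4,
    "Gab2": 3e4,
    "Pi3k": 2e4,
    "Btk": 2e4,
    "Plcg1": 2e4,
    "PI45P2": 3e5,
    "PI4P": 1e5,
    "Grap2": 3e4,
    "Lcp2": 3e4,
}

#: Relative Syk-activity levels of the clamped-input simulations (the "high"
#: and "intermediate" stimulation conditions; the high condition saturates
#: Lat phosphorylation so the two conditions differ about fourfold in Lat-P)
SYK_HIGH = 1.0
SYK_INTERMEDIATE = 0.05
SYK_PANEL = (1.0, 0.25, 0.1, 0.05, 0.02)


def default_seed_amounts() -> dict:
    return dict(_DEFAULT_SEEDS)


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

@dataclass
class ModelSelection:
    """A choice of sub-libraries / rule numbers plus model configuration."""

    sublibraries: tuple = ()
    rule_numbers: Optional[tuple] = None       # restrict numbered rules
    include_gab2_feedback: bool = False        # Rule 15 + membrane companions
    include_plcg2: bool = False                # rules 31-37
    include_btk_on_plcg2: bool = False
    seeds: dict = field(default_factory=dict)  # species text -> amount
    observables: list = field(default_factory=list)
    parameter_overrides: dict = field(default_factory=dict)
    phosphatase_exclude: tuple = ()            # (molecule, site) pairs


class SelectionError(ValueError):
    """A selection referencing molecules absent from the library."""


def _entry_types(entry: LibraryEntry) -> set:
    rule = entry.parse()
    names = set()
    for p in rule.reactants + rule.products:
        names |= set(m.name for m in p.molecules)
    return names


def build_model(selection: ModelSelection) -> Model:
    """Assemble a self-contained model from a library selection.

    The returned model contains exactly the molecule types used by the
    selected rules and seeds, the full default parameter set (with
    overrides applied), the requested seed species, and the selected rules.
    Implicit phosphatase rules, when selected, are generated for the
    phosphosites of the model's own molecule types only.
    """
    index = library_index()
    entries: list = []
    for sub in selection.sublibraries:
        if sub == "implicit_phosphatase":
            continue  # generated after the type closure is known
        if sub not in index:
            raise SelectionError(f"unknown sub-library {sub!r}")
        for e in index[sub]:
            if sub == "lat_downstream":
                if selection.rule_numbers is not None and \
                        e.number not in selection.rule_numbers:
                    continue
                if not selection.include_plcg2 and 31 <= e.number <= 37:
                    continue
                if not selection.include_gab2_feedback and e.number == 15:
                    continue
            entries.append(e)
    if selection.include_gab2_feedback and \
            "gab2_feedback" not in selection.sublibraries:
        added_numbers = {e.number for e in entries if e.number is not None}
        entries.extend(e for e in index["gab2_feedback"]
                       if e.number is None or e.number not in added_numbers)
    if selection.include_btk_on_plcg2:
        entries.extend(index["btk_on_plcg2"])

    model = Model(parameters=default_parameters().updated(
        selection.parameter_overrides))

    if not entries and not selection.seeds:
        # an empty selection still exposes the library's molecule type table
        model.molecule_types = dict(MOLECULE_TYPES)
        model.observables = list(selection.observables)
        return model

    used_types: set = set()
    for e in entries:
        used_types |= _entry_types(e)
    seeds = []
    for text, amount in selection.seeds.items():
        graph = parse_complex(text)
        missing = graph.type_names() - set(MOLECULE_TYPES)
        if missing:
            raise SelectionError(
                f"seed {text!r} uses undeclared molecule types: {sorted(missing)}"
            )
        used_types |= set(graph.type_names())
        seeds.append((graph, amount))

    if "implicit_phosphatase" in selection.sublibraries:
        entries.extend(implicit_phosphatase_entries(
            type_names=used_types, exclude=selection.phosphatase_exclude))

    for name in MOLECULE_TYPES:
        if name in used_types:
            model.molecule_types[name] = MOLECULE_TYPES[name]
    model.seeds = seeds
    model.rules = [e.parse() for e in entries]
    model.observables = list(selection.observables)
    model.validate()
    return model


def default_observables(grap2_loop: bool = False) -> list:
    """The readouts tracked in the reduced Lat-branch models."""
    obs = [
        Observable("LatY136P", "Molecules", [parse_complex("Lat(Y136~P!?)")]),
        Observable("LatY175P", "Molecules", [parse_complex("Lat(Y175~P!?)")]),
        # active Plcg1: recruited (SH2 bound) and phosphorylated
        Observable("ActivePlcg1", "Molecules",
                   [parse_complex("Plcg1(SH2!+,Y783~P)")]),
        # active Btk: recruited to PIP3
        Observable("ActiveBtk", "Molecules", [parse_complex("Btk(PH!+)")]),
        # PI3K in a Lat-nucleated complex
        Observable("LatPI3K", "Molecules", [parse_complex(
            "Lat(Y175~P!1).Grb2(SH2!1,cSH3!2).Gab2(PRS!2,Y441~P!3).Pi3k(p85_SH2!3)"
        )]),
        Observable("PIP3", "Molecules", [parse_complex("PI345P3()")]),
        Observable("IP3", "Molecules", [parse_complex("IP3()")]),
        Observable("ActiveSyk", "Molecules", [parse_complex("Syk(tSH2!+)")]),
        Observable("ActiveFyn", "Molecules", [parse_complex("Fyn(U!+)")]),
    ]
    return obs


# numbered rules of the initial feed-forward-loop model (Lat branch without
# the Grap2/Lcp2 arm and without Plcg2/Inpp5d)
_FFL_RULES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 12, 14, 16, 17, 18, 19, 20,
              21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 49, 50, 51)
_FFL_RULES_GRAP2 = _FFL_RULES + (10, 11, 13)


def ffl_model(
    feedback: bool = False,
    input_mode: str = "signal",
    signal: float = 0.01,
    syk_level: float = 1.0,
    fyn_level: float = 1.0,
    grap2_loop: bool = False,
    seeds: Optional[dict] = None,
    parameter_overrides: Optional[dict] = None,
) -> Model:
    """The example models: branching pathways from Lat to PIP3 and IP3.

    ``feedback=False`` builds the initial model (first coherent feed-forward
    loop: Lat recruits Plcg1 directly, and PI3K via Grb2/Gab2; Btk binds
    PIP3 and phosphorylates Plcg1; Fyn phosphorylates Gab2).
    ``feedback=True`` adds the Gab2--PIP3 positive-feedback interactions.

    ``input_mode`` selects how Syk and Fyn are activated:

    * ``"signal"`` -- both kinases are activated at a rate proportional to
      the inactive amount with shared strength ``signal`` (the bifurcation
      parameter) and deactivate through first-order processes;
    * ``"clamped"`` -- fixed fractions ``syk_level``/``fyn_level`` of the
      kinase pools are seeded in the active, membrane-anchored form and no
      activation/deactivation occurs (constant activity over time).
    """
    amounts = default_seed_amounts()
    if seeds:
        amounts.update(seeds)
    sel_seeds: dict = {}

    def seed_protein(text_active, text_inactive, total, active_fraction):
        act = total * active_fraction
        if act > 0:
            sel_seeds[text_active] = act
        if total - act > 0:
            sel_seeds[text_inactive] = total - act

    if input_mode == "clamped":
        seed_protein(
            "Syk(tSH2!1,PTK,Y519_Y520~P).Anchor(a!1)",
            "Syk(tSH2,PTK,Y519_Y520~0)",
            amounts["Syk"], syk_level)
        seed_protein(
            "Fyn(U!1,SH2,SH3,PTK,Yc~0).Anchor(a!1)",
            "Fyn(U,SH2,SH3,PTK,Yc~0)",
            amounts["Fyn"], fyn_level)
        sublibs = ("lat_downstream", "lipid_background", "implicit_phosphatase")
        overrides = dict(parameter_overrides or {})
    elif input_mode == "signal":
        sel_seeds["Syk(tSH2,PTK,Y519_Y520~0)"] = amounts["Syk"]
        sel_seeds["Fyn(U,SH2,SH3,PTK,Yc~0)"] = amounts["Fyn"]
        sublibs = ("lat_downstream", "lipid_background", "implicit_phosphatase",
                   "input_signal")
        overrides = {"signal": signal}
        overrides.update(parameter_overrides or {})
    else:
        raise ValueError(f"unknown input_mode {input_mode!r}")

    sel_seeds["Lat(Y136~0,Y175~0)"] = amounts["Lat"]
    sel_seeds["Grb2(SH2,cSH3)"] = amounts["Grb2"]
    sel_seeds["Gab2(PRS,PH,Y441~0)"] = amounts["Gab2"]
    sel_seeds["Pi3k(p85_SH2,PI3Kc)"] = amounts["Pi3k"]
    sel_seeds["Btk(PH,PTK)"] = amounts["Btk"]
    sel_seeds["Plcg1(SH2,SH3,PLC,Y783~0)"] = amounts["Plcg1"]
    sel_seeds["PI45P2(headgroup)"] = amounts["PI45P2"]
    sel_seeds["PI4P(headgroup)"] = amounts["PI4P"]
    if grap2_loop:
        sel_seeds["Grap2(SH2,SH3)"] = amounts["Grap2"]
        sel_seeds["Lcp2(RxxK,PRS)"] = amounts["Lcp2"]

    selection = ModelSelection(
        sublibraries=sublibs,
        rule_numbers=_FFL_RULES_GRAP2 if grap2_loop else _FFL_RULES,
        include_gab2_feedback=feedback,
        seeds=sel_seeds,
        observables=default_observables(grap2_loop),
        parameter_overrides=overrides,
        # the Syk activation loop is controlled by the input, not by the
        # generic phosphatase background
        phosphatase_exclude=(("Syk", "Y519_Y520"),),
    )
    return build_model(selection)


def write_sublibrary_text(sublibrary: str) -> str:
    """One sub-library as a standalone BNGL-subset fragment."""
    index = library_index()
    if sublibrary not in index:
        raise SelectionError(f"unknown sub-library {sublibrary!r}")
    entries = index[sublibrary]
    types = set()
    for e in entries:
        types |= _entry_types(e)
    out = ["begin molecule types"]
    for name in MOLECULE_TYPES:
        if name in types:
            out.append(f"  {MOLECULE_TYPES[name].to_text()}")
    out.append("end molecule types")
    out.append("begin reaction rules")
    for e in entries:
        out.append(f"  {e.name}: {e.text}")
    out.append("end reaction rules")
    return "\n".join(out) + "\n"
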