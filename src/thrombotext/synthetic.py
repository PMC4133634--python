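"""Synthetic sectioned radiology reports with gold annotations and labels.

Real CTA/CTV reports cannot be redistributed, so every downstream stage
is exercised on generated corpora instead.  Reports are built from
templated French sentences with randomized slot fillers drawn from the
bundled lexicon; every inserted concept mention is recorded as a gold
annotation together with its modality and Location_of / Reveals
relations, and each report receives gold PE / DVT / incidentaloma
labels whose content consistency is enforced by construction:

* pe=1 reports assert a thromboembolic concept (Positive modality)
  located in pulmonary vasculature in both results and conclusion;
  pe=0 reports mention the same vocabulary under negation or hypothesis
  cues ("pas de", "absence de", "doute sur", ...);
* dvt behaves identically with limb-vein anatomy;
* incidentaloma=1 reports carry a clinically relevant finding (K) with
  Incidental modality in the results section only — incidental findings
  are typically not restated in the conclusion, which re-iterates the
  findings relevant to the exam's indication.

Default class prevalences follow the joint CTA/CTV outcome distribution
observed on the 573-report study corpus: 12.9% both positive, 9.1%
PE only, 5.2% DVT only, 72.8% both negative, with a 16.2% marginal
incidentaloma rate.

The generator is not a language model: its prose is deterministic,
inspectable and far more regular than real clinical French.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AnnotationSet,
    ConceptAnnotation,
    ConceptType,
    GoldLabels,
    Modality,
    ModalityAnnotation,
    RelationAnnotation,
    RelationType,
    Report,
)
from .preprocess import fold, split_sections

#: Joint (pe, dvt) outcome probabilities on the study corpus.
DEFAULT_JOINT_PE_DVT: dict[tuple[int, int], float] = {
    (1, 1): 0.129,
    (1, 0): 0.091,
    (0, 1): 0.052,
    (0, 0): 0.728,
}
DEFAULT_INCIDENTALOMA_RATE = 0.162

#: Abbreviation / spelling-variant table used by perturb_spelling.
ABBREVIATION_VARIANTS: dict[str, tuple[str, ...]] = {
    "phléboscan": ("phlebo-scan", "phleboscan"),
    "phlebo-scan": ("phléboscan",),
    "embolie pulmonaire": ("EP",),
    "thrombose veineuse profonde": ("TVP",),
    "angioscanner thoracique": ("angioscanner du thorax",),
}

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def perturb_spelling(
    term: str,
    rng: np.random.Generator,
    abbreviations: dict[str, tuple[str, ...]] | None = None,
) -> str:
    """Return an abbreviation variant or a single-character edit of term.

    Emulates the spelling errors and abbreviations that cause keyword
    queries and dictionary matchers to miss mentions.  The output is
    either a listed variant of the term or at Levenshtein distance <= 1
    from it.
    """
    if not term:
        raise ValueError("cannot perturb an empty term")
    if abbreviations is None:
        abbreviations = ABBREVIATION_VARIANTS
    variants = abbreviations.get(term)
    if variants and rng.random() < 0.5:
        return variants[rng.integers(len(variants))]
    op = rng.choice(["delete", "insert", "substitute"])
    pos = int(rng.integers(len(term)))
    if op == "delete" and len(term) > 1:
        return term[:pos] + term[pos + 1:]
    ch = _ALPHABET[rng.integers(len(_ALPHABET))]
    if op == "insert":
        return term[:pos] + ch + term[pos:]
    return term[:pos] + ch + term[pos + 1:]


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int
    joint_pe_dvt: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_JOINT_PE_DVT)
    )
    incidentaloma_rate: float = DEFAULT_INCIDENTALOMA_RATE
    seed: int = 0
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        expected = {(1, 1), (1, 0), (0, 1), (0, 0)}
        if set(self.joint_pe_dvt) != expected:
            raise ValueError(
                "joint_pe_dvt must cover the four (pe, dvt) outcomes"
            )
        probs = list(self.joint_pe_dvt.values()) + [
            self.incidentaloma_rate, self.noise
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.joint_pe_dvt.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"joint (pe, dvt) probabilities sum to {total}, expected 1"
            )


# ---------------------------------------------------------------------------
# vocabulary (every slot term below is an entry of the bundled lexicon)

PULMONARY_SITES = (
    "artère pulmonaire droite",
    "artère pulmonaire gauche",
    "artères pulmonaires",
    "tronc de l'artère pulmonaire",
    "artère lobaire inférieure droite",
    "artère lobaire supérieure gauche",
    "artère segmentaire",
)
VENOUS_SITES = (
    "veine fémorale commune",
    "veine fémorale superficielle",
    "veine poplitée droite",
    "veine poplitée gauche",
    "veine iliaque externe",
    "veines surales",
    "veine cave inférieure",
)
LUNG_SITES = (
    "lobe supérieur droit",
    "lobe supérieur gauche",
    "lobe inférieur droit",
    "lobe inférieur gauche",
    "lobe moyen",
)
ORGAN_SITES = (
    "foie", "rein droit", "rein gauche", "surrénale droite",
    "surrénale gauche", "thyroïde", "médiastin", "pancréas", "rate",
)
PE_TERMS = ("embolie pulmonaire", "embolie pulmonaire bilatérale", "embolie",
            "EP")
DVT_TERMS = ("thrombose veineuse profonde", "thrombose veineuse", "thrombose",
             "TVP")
GENERIC_CLOT_TERMS = ("thrombus", "défect endoluminal")
FINDING_TERMS = ("nodule", "nodule pulmonaire", "micronodule", "masse",
                 "masse suspecte", "adénopathie", "adénopathies", "kyste",
                 "lésion nodulaire")

_PE_TERMS_FOLDED = frozenset(fold(t) for t in PE_TERMS)
_DVT_TERMS_FOLDED = frozenset(fold(t) for t in DVT_TERMS)
_PULMONARY_FOLDED = frozenset(fold(t) for t in PULMONARY_SITES)
_VENOUS_FOLDED = frozenset(fold(t) for t in VENOUS_SITES)

_NAMES = ("MARTIN", "BERNARD", "DUBOIS", "THOMAS", "ROBERT", "RICHARD",
          "PETIT", "DURAND", "LEROY", "MOREAU", "SIMON", "LAURENT")
# Neutral observations reuse the same assertion and negation cue words
# as the diagnostic statements, so no cue token alone betrays a label.
_FILLER_RESULTS = (
    "Absence d'épanchement pleural ou péricardique.",
    "Parenchyme de densité normale, sans condensation alvéolaire.",
    "Bonne opacification de l'ensemble des axes vasculaires.",
    "Pas d'anomalie de la paroi ni des parties molles.",
    "Structures osseuses sans particularité.",
    "Présence d'un cathéter veineux central en place.",
    "Mise en évidence de plaques calcifiées aortiques sans sténose.",
    "Visualisation satisfaisante des cavités cardiaques.",
    "On retrouve quelques troubles ventilatoires des bases.",
    "Doute sur un artéfact de mouvement en fenêtre parenchymateuse.",
    "Résultats à confronter aux données cliniques.",
    "Le reste de l'examen est sans particularité.",
)


class _Builder:
    """Accumulates report text and gold annotations with running offsets."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.chunks: list[str] = []
        self.length = 0
        self.annset = AnnotationSet()

    def add(self, s: str) -> None:
        self.chunks.append(s)
        self.length += len(s)

    def concept(
        self,
        term: str,
        ctype: ConceptType,
        modality: Modality | None = None,
    ) -> str:
        surface = term
        if self.cfg.noise > 0 and self.rng.random() < self.cfg.noise:
            surface = perturb_spelling(term, self.rng)
        tid = f"T{len(self.annset.concepts) + 1}"
        start = self.length
        self.add(surface)
        self.annset.concepts.append(
            ConceptAnnotation(tid, ctype, start, start + len(surface),
                              surface)
        )
        if modality is not None:
            aid = f"A{len(self.annset.modalities) + 1}"
            self.annset.modalities.append(
                ModalityAnnotation(aid, tid, modality)
            )
        return tid

    def relation(self, rtype: RelationType, arg1: str, arg2: str) -> None:
        rid = f"R{len(self.annset.relations) + 1}"
        self.annset.relations.append(
            RelationAnnotation(rid, rtype, arg1, arg2)
        )

    def located(
        self,
        term: str,
        ctype: ConceptType,
        site: str,
        modality: Modality | None = None,
        glue: str = " de ",
    ) -> str:
        cid = self.concept(term, ctype, modality)
        self.add(glue)
        sid = self.concept(site, ConceptType.ANATOMY)
        self.relation(RelationType.LOCATION_OF, cid, sid)
        return cid

    @property
    def text(self) -> str:
        return "".join(self.chunks)


def _pick(rng: np.random.Generator, seq) -> str:
    return seq[int(rng.integers(len(seq)))]


def _generate_report(
    index: int,
    pe: int,
    dvt: int,
    inc: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[Report, AnnotationSet]:
    b = _Builder(cfg, rng)
    report_id = f"r{index:04d}"

    # --- identification -------------------------------------------------
    b.add("IDENTIFICATION :\n")
    name = _pick(rng, _NAMES)
    civ = _pick(rng, ("Mme", "M.", "Mlle"))
    byear = 1930 + int(rng.integers(60))
    b.add(f"{civ} {name}, né(e) en {byear}. Examen du "
          f"{int(rng.integers(1, 29)):02d}/{int(rng.integers(1, 13)):02d}"
          f"/2011.\n")

    # --- indication -----------------------------------------------------
    b.add(_pick(rng, ("INDICATION :", "Indication :")) + "\n")
    symptom = _pick(rng, ("Dyspnée aiguë.", "Douleur thoracique brutale.",
                          "Désaturation inexpliquée.",
                          "Tachycardie et douleur basithoracique."))
    b.add(symptom + " Suspicion d'")
    b.concept("embolie pulmonaire", ConceptType.THROMBO_PAT,
              Modality.HYPOTHETICAL)
    b.add(".")
    if rng.random() < 0.06:
        b.add(" Patiente en ")
        b.concept("post-partum", ConceptType.PP)
        b.add(" après ")
        b.concept(_pick(rng, ("accouchement", "césarienne")), ConceptType.PP)
        b.add(".")
    b.add("\n")

    # --- protocol ---------------------------------------------------------
    b.add(_pick(rng, ("TECHNIQUE :", "Technique :", "PROTOCOLE :")) + "\n")
    b.add("Réalisation d'un ")
    cta_id = b.concept(
        _pick(rng, ("angioscanner thoracique", "angioscanner du thorax")),
        ConceptType.EXAM,
    )
    b.add(" complété par un ")
    b.concept(_pick(rng, ("phléboscan", "phlebo-scan")), ConceptType.EXAM)
    b.add(" des membres après injection de produit de contraste iodé.\n")

    # --- results ----------------------------------------------------------
    b.add(_pick(rng, ("RESULTATS :", "Résultats :", "RESULTAT :")) + "\n")
    pe_concept_results = None

    # thromboembolic statements, pulmonary then venous
    # Positive and negative statements share glue phrases and site
    # mentions so that the assertion is carried by cue words that also
    # occur elsewhere, not by sentence-unique vocabulary.
    pe_glues = (" au niveau de l'", " dans le territoire de l'",
                " intéressant l'")
    if pe:
        variant = rng.random()
        if variant < 0.5:
            b.add(_pick(rng, ("Présence d'une ", "Mise en évidence d'une ",
                              "Visualisation d'une ")))
            pe_concept_results = b.located(
                "embolie pulmonaire", ConceptType.THROMBO_PAT,
                _pick(rng, PULMONARY_SITES), Modality.POSITIVE,
                glue=_pick(rng, pe_glues),
            )
        else:
            b.add(_pick(rng, ("Visualisation d'un ", "Présence d'un ",
                              "Mise en évidence d'un ")))
            pe_concept_results = b.located(
                _pick(rng, GENERIC_CLOT_TERMS), ConceptType.THROMBO_PAT,
                _pick(rng, PULMONARY_SITES), Modality.POSITIVE,
                glue=_pick(rng, pe_glues),
            )
        b.add(".")
    else:
        r = rng.random()
        if r < 0.35:
            b.add("Pas d'")
            b.concept("embolie pulmonaire", ConceptType.THROMBO_PAT,
                      Modality.NEGATIVE)
            b.add(" décelée.")
        elif r < 0.65:
            b.add("Absence d'")
            b.located("embolie pulmonaire", ConceptType.THROMBO_PAT,
                      "artères pulmonaires", Modality.NEGATIVE,
                      glue=" au niveau des ")
            b.add(".")
        elif r < 0.9:
            b.add("Pas de ")
            b.located(_pick(rng, GENERIC_CLOT_TERMS),
                      ConceptType.THROMBO_PAT,
                      _pick(rng, PULMONARY_SITES), Modality.NEGATIVE,
                      glue=_pick(rng, pe_glues))
            b.add(".")
        else:
            b.add("Doute sur une ")
            b.located("embolie", ConceptType.THROMBO_PAT,
                      _pick(rng, PULMONARY_SITES), Modality.HYPOTHETICAL,
                      glue=_pick(rng, pe_glues))
            b.add(", à confronter aux données cliniques.")
    b.add("\n")

    if dvt:
        if rng.random() < 0.5:
            b.add(_pick(rng, ("Mise en évidence d'une ", "Présence d'une ",
                              "Visualisation d'une ")))
            b.located(_pick(rng, ("thrombose veineuse profonde",
                                  "thrombose veineuse")),
                      ConceptType.THROMBO_PAT,
                      _pick(rng, VENOUS_SITES), Modality.POSITIVE,
                      glue=" de la ")
        else:
            b.add(_pick(rng, ("Visualisation d'un ", "Présence d'un ")))
            b.located("thrombus", ConceptType.THROMBO_PAT,
                      _pick(rng, VENOUS_SITES), Modality.POSITIVE,
                      glue=" occlusif de la ")
        b.add(".")
        if rng.random() < 0.5:
            b.add(" Le reste du réseau veineux profond est perméable.")
    else:
        r = rng.random()
        if r < 0.4:
            b.add("Pas de ")
            b.concept(_pick(rng, ("thrombose veineuse", "thrombose")),
                      ConceptType.THROMBO_PAT, Modality.NEGATIVE)
            b.add(" décelée.")
        elif r < 0.7:
            b.add("Pas de ")
            b.located("thrombus", ConceptType.THROMBO_PAT,
                      _pick(rng, VENOUS_SITES), Modality.NEGATIVE,
                      glue=" occlusif de la ")
            b.add(".")
        else:
            b.add("L'ensemble du réseau veineux profond est perméable, "
                  "absence de ")
            b.concept("thrombose veineuse", ConceptType.THROMBO_PAT,
                      Modality.NEGATIVE)
            b.add(".")
    b.add("\n")

    # incidental finding (results only) and known/negated distractors
    if inc:
        kind = rng.random()
        if kind < 0.5:
            term, site = (_pick(rng, ("nodule pulmonaire", "nodule",
                                      "micronodule")),
                          _pick(rng, LUNG_SITES))
            glue = " du "
        elif kind < 0.8:
            term, site = (_pick(rng, ("masse", "masse suspecte",
                                      "lésion nodulaire", "kyste")),
                          _pick(rng, ORGAN_SITES))
            glue = " de la " if site in (
                "surrénale droite", "surrénale gauche", "thyroïde", "rate"
            ) else " du "
        else:
            term, site = (_pick(rng, ("adénopathie", "adénopathies")),
                          "médiastin")
            glue = " du "
        b.add(_pick(rng, ("Présence d'un ", "Mise en évidence d'un ",
                          "On retrouve un ")))
        b.located(term, ConceptType.K, site, Modality.INCIDENTAL, glue=glue)
        b.add(f" de {int(rng.integers(5, 30))} mm")
        if rng.random() < 0.5:
            b.add(", de découverte fortuite")
        b.add(".\n")
    known_distractor = None
    if rng.random() < 0.35:
        if rng.random() < 0.5:
            b.add("Présence d'un ")
            term, site = _pick(rng, ("kyste", "nodule", "masse")), _pick(
                rng, ORGAN_SITES)
            known_distractor = (term, site)
            b.located(term, ConceptType.K, site, Modality.KNOWN, glue=" du ")
            b.add(f" de {int(rng.integers(5, 30))} mm déjà connu, "
                  "inchangé.\n")
        else:
            b.add("Pas de ")
            b.concept(_pick(rng, ("masse suspecte", "adénopathie")),
                      ConceptType.K, Modality.NEGATIVE)
            b.add(" décelée.\n")
    for filler in rng.choice(_FILLER_RESULTS, size=3, replace=False):
        b.add(str(filler) + "\n")

    # --- conclusion -------------------------------------------------------
    b.add(_pick(rng, ("CONCLUSION :", "Conclusion :")) + "\n")
    if pe:
        pe_id = b.concept("embolie pulmonaire", ConceptType.THROMBO_PAT,
                          Modality.POSITIVE)
        if rng.random() < 0.5:
            b.add(" au niveau de l'")
            sid = b.concept(_pick(rng, PULMONARY_SITES), ConceptType.ANATOMY)
            b.relation(RelationType.LOCATION_OF, pe_id, sid)
        b.add(".")
        if rng.random() < 0.15:
            b.relation(RelationType.REVEALS, cta_id,
                       pe_concept_results or pe_id)
    else:
        if rng.random() < 0.05:
            b.add("L'examen ne permet pas d'exclure une ")
            b.concept("embolie pulmonaire", ConceptType.THROMBO_PAT,
                      Modality.HYPOTHETICAL)
            b.add(".")
        else:
            b.add("Absence d'")
            b.concept("embolie pulmonaire", ConceptType.THROMBO_PAT,
                      Modality.NEGATIVE)
            b.add(".")
    b.add(" ")
    if dvt:
        did = b.concept("thrombose veineuse profonde",
                        ConceptType.THROMBO_PAT, Modality.POSITIVE)
        if rng.random() < 0.5:
            b.add(" de la ")
            sid = b.concept(_pick(rng, VENOUS_SITES), ConceptType.ANATOMY)
            b.relation(RelationType.LOCATION_OF, did, sid)
        b.add(".")
    else:
        b.add("Pas de ")
        b.concept("thrombose veineuse profonde", ConceptType.THROMBO_PAT,
                  Modality.NEGATIVE)
        b.add(".")
    if known_distractor is not None and rng.random() < 0.5:
        term, site = known_distractor
        b.add(" ")
        b.located(term, ConceptType.K, site, Modality.KNOWN, glue=" du ")
        b.add(" connu.")
    b.add("\n")

    text = b.text
    report = Report(report_id, text, split_sections(text))
    b.annset.validate(text)
    return report, b.annset


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Report], dict[str, AnnotationSet], dict[str, GoldLabels]]:
    """Generate a labelled, gold-annotated corpus, reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    outcomes = list(config.joint_pe_dvt.items())
    probs = np.array([p for _, p in outcomes])
    probs = probs / probs.sum()

    reports: list[Report] = []
    annsets: dict[str, AnnotationSet] = {}
    labels: dict[str, GoldLabels] = {}
    for i in range(config.n_reports):
        (pe, dvt), _ = outcomes[int(rng.choice(len(outcomes), p=probs))]
        inc = int(rng.random() < config.incidentaloma_rate)
        report, annset = _generate_report(i, pe, dvt, inc, config, rng)
        reports.append(report)
        annsets[report.report_id] = annset
        labels[report.report_id] = GoldLabels(report.report_id, pe, dvt, inc)
    return reports, annsets, labels


def labels_from_annotations(annset: AnnotationSet) -> tuple[int, int, int]:
    """Oracle: recover (pe, dvt, incidentaloma) from gold annotations.

    A report is PE-positive when some thromboembolic concept carries a
    Positive modality and is located in (or names) pulmonary
    vasculature; DVT-positive analogously for limb/deep veins; and
    incidentaloma-positive when any clinically relevant finding carries
    the Incidental modality.
    """
    by_id = annset.concept_by_id()
    positive_ids = {
        m.target for m in annset.modalities
        if m.modality is Modality.POSITIVE
    }
    loc_site: dict[str, str] = {}
    for r in annset.relations:
        if r.relation_type is RelationType.LOCATION_OF:
            loc_site[r.arg1] = fold(by_id[r.arg2].surface)

    pe = dvt = 0
    for cid in positive_ids:
        c = by_id[cid]
        if c.concept_type is not ConceptType.THROMBO_PAT:
            continue
        site = loc_site.get(cid)
        surface = fold(c.surface)
        if site in _PULMONARY_FOLDED or surface in _PE_TERMS_FOLDED:
            pe = 1
        if site in _VENOUS_FOLDED or surface in _DVT_TERMS_FOLDED:
            dvt = 1
    inc = int(any(
        m.modality is Modality.INCIDENTAL
        and by_id[m.target].concept_type is ConceptType.K
        for m in annset.modalities
    ))
    return pe, dvt, inc
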