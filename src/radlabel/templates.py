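"""Sentence-template inventory for the synthetic neuroradiology corpus.

The inventory is versioned data. Reports are assembled from an optional
protocol/clinical-history block, a findings block, and a conclusion block.

Finding mentions — positive and negated alike — share one grammar::

    {opener} {det} {m1} {m2} {m3} {connector} {finding}.

with ``det = "a"`` asserting the finding and ``det = "no"`` negating it.
The polarity cue is therefore separated from the finding lexicon by at
least four tokens (three modifier words plus a multi-word connector):
distant negation. Neutral sentences that occur in normal and abnormal
reports alike reuse the same determiner + modifier windows ("there is no
convincing imaging artefact …"), so every word window of three tokens or
fewer is class-ambiguous by construction; only longer-range context
resolves whether a finding is asserted or negated.
"""

TEMPLATE_VERSION = "2"

CATEGORIES = (
    "acute_stroke",
    "mass",
    "atrophy",
    "vascular",
    "small_vessel_disease",
    "white_matter_inflammation",
    "encephalomalacia",
)

ALL_LABELS = ("abnormal",) + CATEGORIES

# >=5 phrasings per category (article-free; the mention grammar supplies
# the determiner).
FINDING_PHRASES = {
    "acute_stroke": (
        "acute infarction",
        "restricted diffusion from acute ischaemia",
        "acute ischaemic stroke",
        "acute territorial infarction",
        "acute cytotoxic oedema",
    ),
    "mass": (
        "mass lesion",
        "enhancing intracranial mass",
        "space occupying lesion",
        "extra axial mass",
        "tumour with surrounding oedema",
    ),
    "atrophy": (
        "volume loss in excess of age",
        "disproportionate parenchymal atrophy",
        "hippocampal volume loss",
        "global cerebral atrophy",
        "temporal lobe atrophy",
    ),
    "vascular": (
        "saccular aneurysm",
        "vascular malformation",
        "multiple microhaemorrhages",
        "arteriovenous fistula",
        "carotid dissection",
    ),
    "small_vessel_disease": (
        "moderate small vessel disease",
        "severe small vessel ischaemic change",
        "confluent deep white matter small vessel change",
        "periventricular small vessel disease",
        "advanced small vessel ischaemic damage",
    ),
    "white_matter_inflammation": (
        "demyelinating white matter lesions",
        "inflammatory white matter change",
        "periventricular demyelination",
        "active demyelinating plaques",
        "tumefactive demyelination",
    ),
    "encephalomalacia": (
        "established encephalomalacia",
        "gliosis from an old infarct",
        "chronic post surgical parenchymal damage",
        "encephalomalacic change from previous haemorrhage",
        "mature cortical defect with gliosis",
    ),
}

# Benign findings reported with the same mention grammar as pathological
# ones, asserted or negated in normal and abnormal reports alike. They keep
# every determiner word-window class-ambiguous: a bag of <=3-grams can count
# asserted and negated mentions but cannot tell WHICH finding a determiner
# belongs to.
BENIGN_FINDING_PHRASES = (
    "prominent perivascular spaces",
    "incidental arachnoid granulation",
    "physiological pineal calcification",
    "minor mucosal thickening",
    "normal developmental variant",
    "well defined perivascular space",
)

OPENERS = (
    "there is",
    "this study shows",
    "on review there is",
    "within the brain parenchyma there is",
    "on the current examination there is",
)

MOD1 = ("convincing", "definite", "significant", "discrete", "focal")
MOD2 = ("imaging", "signal", "radiological", "parenchymal")
MOD3 = ("feature", "abnormality", "appearance", "change", "correlate")

CONNECTORS = (
    "in keeping with",
    "consistent with",
    "suggestive of",
    "to indicate",
    "of",
)

HEDGES = ("possibly", "probably", "perhaps")

# Neutral sentences covering both determiners' local word windows; these
# occur in normal and abnormal reports alike.
NEUTRAL_DET_SENTENCES = (
    "midline shift is not demonstrated.",
    "no hydrocephalus or extra axial collection.",
)

NORMAL_STATEMENTS = (
    "normal intracranial appearances.",
    "the intracranial appearances are within normal limits.",
    "appearances are unremarkable for age.",
)

REASSURANCE_STATEMENTS = (
    "the appearances are otherwise within normal limits.",
    "the intracranial appearances are elsewhere preserved.",
    "the remaining sequences are within normal limits.",
)

HISTORY_SENTENCES = (
    "clinical history of headache and visual disturbance.",
    "clinical details recent fall with confusion.",
    "referred with progressive memory impairment.",
    "clinical history of seizures under investigation.",
    "known hypertension presenting with dysphasia.",
)

PROTOCOL_SENTENCES = (
    "mri head performed with standard departmental protocol.",
    "axial t2 flair diffusion and susceptibility weighted sequences acquired.",
    "volumetric t1 and coronal t2 sequences were obtained.",
    "study performed with and without intravenous contrast.",
)

FILLER_SENTENCES = (
    "the major intracranial flow voids are maintained.",
    "the orbits and paranasal sinuses are otherwise clear.",
    "the craniocervical junction is satisfactory.",
    "midline structures are in normal position.",
    "the pituitary gland is of normal size and signal.",
    "mastoid air cells are well aerated.",
    "the calvarium returns normal marrow signal.",
    "the appearances are in keeping with the stated age.",
    "the ventricular volumes are consistent with the stated age.",
)

CONCLUSION_SENTENCES = (
    "findings as discussed above.",
    "clinical correlation is advised.",
    "comparison with any prior imaging is recommended.",
    "discussed findings communicated to the referring team.",
    "follow up imaging may be considered if clinically indicated.",
)
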