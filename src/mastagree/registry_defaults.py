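"""Shipped default panel registry and allergen alias table.

The default registry covers the four immunoblot MAST analyzers commonly
compared in Korean laboratories.  Panel memberships are assembled from
published comparison tables, not from vendor panel sheets, so they are a
best-effort default: full panels are larger than what is listed here (see
``EXPECTED_PANEL_COUNTS``), and :meth:`PanelRegistry.check_counts` treats
mismatches as warnings rather than errors.  Users comparing real exports
should load their own registry with :func:`mastagree.io.load_registry`.
"""

from __future__ import annotations

from .model import Panel, PanelRegistry

ALLOSCREEN = "alloscreen"
SMART2 = "smart2"
PROTIA = "protia"
RIDA = "rida"

ANALYZER_IDS = (ALLOSCREEN, SMART2, PROTIA, RIDA)

# Allergens appearing in food-panel comparisons of at least two analyzers.
_FOOD_SHARED = [
    "alternaria alternata",
    "anchovy",
    "aspergillus fumigatus",
    "banana",
    "barley meal",
    "beef",
    "birch-alder mix",
    "bromelain (ccd)",
    "buck-wheat",
    "candida albicans",
    "cat",
    "cheddar cheese",
    "chestnut",
    "chicken",
    "citrus mix",
    "cladosporium herbarum",
    "clam",
    "cockroach",
    "codfish",
    "crab",
    "cucumber",
    "dermatophagoides farinae",
    "dermatophagoides pteronyssinus",
    "dog",
    "egg white",
    "garlic",
    "house dust",
    "japanese hop",
    "kiwi",
    "latex",
    "mackerel",
    "mango",
    "milk",
    "mugwort",
    "mussel",
    "oak white",
    "onion",
    "peach",
    "peanut",
    "pork",
    "potato",
    "pupa, silk cocoon",
    "ragweed",
    "rice",
    "rye pollens",
    "salmon",
    "shrimp",
    "soy bean",
    "storage mite",
    "tomato",
    "tuna",
    "wheat flour",
    "yeast, bakers",
]

# Allergens appearing in inhalant-panel comparisons of at least two analyzers.
_INHALANT_SHARED = [
    "acacia",
    "alternaria alternata",
    "ash mix",
    "aspergillus fumigatus",
    "bermuda grass",
    "birch-alder mix",
    "bromelain (ccd)",
    "cat",
    "cladosporium herbarum",
    "cockroach",
    "crab",
    "dandelion",
    "dermatophagoides farinae",
    "dermatophagoides pteronyssinus",
    "dog",
    "egg white",
    "goldenrod",
    "hazelnut",
    "house dust",
    "japanese cedar",
    "japanese hop",
    "latex",
    "mackerel",
    "milk",
    "mugwort",
    "oak white",
    "orchard grass",
    "oxeye daisy",
    "peach",
    "penicillium notatum",
    "pigweed",
    "pine",
    "poplar mix",
    "rabbit",
    "ragweed",
    "redtop, bent grass",
    "reed",
    "russian thistle",
    "rye pollens",
    "sallow willow",
    "shrimp",
    "soy bean",
    "storage mite",
    "sweet vernal grass",
    "sycamore mix",
    "timothy grass",
    "wheat flour",
    "yeast, bakers",
    "yellow jacket (wasp)",
]

# Analyzer-specific allergens (present on exactly one analyzer's panel).
_SPECIFIC = {
    SMART2: {
        Panel.FOOD: ["alder", "celery", "cacao", "maize", "mushroom", "sesame", "squid"],
        Panel.INHALANT: [
            "acarus siro",
            "alder",
            "apple",
            "cacao",
            "english plantain",
            "guinea pig",
            "hamster",
            "hinoki cypress",
            "honey bee",
            "horse",
            "maize",
            "sesame",
            "sheep",
        ],
    },
    PROTIA: {
        Panel.FOOD: ["almond", "lilac", "wool"],
        Panel.INHALANT: ["chocolate", "lilac", "wool"],
    },
    RIDA: {
        Panel.FOOD: ["chocolate"],
        Panel.INHALANT: [],
    },
}

DEFAULT_ALIASES = {
    "d. farinae": "dermatophagoides farinae",
    "d farinae": "dermatophagoides farinae",
    "d. farina": "dermatophagoides farinae",
    "d farina": "dermatophagoides farinae",
    "dermatophagoides farina": "dermatophagoides farinae",
    "d. pteronyssinus": "dermatophagoides pteronyssinus",
    "d pteronyssinus": "dermatophagoides pteronyssinus",
    "birch alder mix": "birch-alder mix",
    "buckwheat": "buck-wheat",
    "soybean": "soy bean",
    "bakers yeast": "yeast, bakers",
    "yeast bakers": "yeast, bakers",
    "bromelain": "bromelain (ccd)",
    "yellow jacket": "yellow jacket (wasp)",
    "wasp": "yellow jacket (wasp)",
    "pupa": "pupa, silk cocoon",
    "pupa silk cocoon": "pupa, silk cocoon",
    "redtop": "redtop, bent grass",
    "redtop bent grass": "redtop, bent grass",
    "egg-white": "egg white",
    "wheat": "wheat flour",
}

# Advertised total panel sizes per analyzer (soft check only).
EXPECTED_PANEL_COUNTS = {
    ALLOSCREEN: {Panel.FOOD: 40, Panel.INHALANT: 40},
    SMART2: {Panel.FOOD: 60, Panel.INHALANT: 60},
    PROTIA: {Panel.FOOD: 44, Panel.INHALANT: 44},
    RIDA: {Panel.FOOD: 60, Panel.INHALANT: 60},
}


def default_registry() -> PanelRegistry:
    """Build the shipped default :class:`PanelRegistry`."""
    panels: dict[str, dict[Panel, list[str]]] = {}
    for analyzer in ANALYZER_IDS:
        panels[analyzer] = {
            Panel.FOOD: list(_FOOD_SHARED),
            Panel.INHALANT: list(_INHALANT_SHARED),
        }
        for panel, extras in _SPECIFIC.get(analyzer, {}).items():
            panels[analyzer][panel] = panels[analyzer][panel] + list(extras)
    return PanelRegistry(panels, aliases=DEFAULT_ALIASES)
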