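"""The 60-noun task vocabulary used for word-arrangement sessions.

Six semantic categories of ten nouns each (humans, non-human animals,
non-animal natural things, constructs, vehicles, other artifacts). The synthetic
generators reuse these labels so that simulated brains, behavioral sessions and
reports all speak the same vocabulary.
"""

from __future__ import annotations

NOUN_CATEGORIES: dict[str, list[str]] = {
    "humans": [
        "employee", "carpenter", "teacher", "student", "driver",
        "player", "actor", "writer", "doctor", "researcher",
    ],
    "animals": [
        "monkey", "dog", "cat", "horse", "cow",
        "sheep", "bird", "frog", "fish", "bug",
    ],
    "natural": [
        "star", "sky", "mountain", "sea", "river",
        "water", "flower", "tree", "dirt", "vegetable",
    ],
    "constructs": [
        "house", "school", "factory", "hospital", "station",
        "airport", "bridge", "hotel", "stadium", "park",
    ],
    "vehicles": [
        "car", "motorbike", "train", "ship", "boat",
        "airplane", "helicopter", "rocket", "bicycle", "carriage",
    ],
    "artifacts": [
        "movie", "book", "music", "phone", "pc",
        "tv", "cloth", "table", "cup", "text",
    ],
}

#: Flat 60-noun list, category blocks in order.
TASK_NOUNS: list[str] = [w for words in NOUN_CATEGORIES.values() for w in words]

#: word -> category lookup for the task nouns.
NOUN_CATEGORY_OF: dict[str, str] = {
    w: cat for cat, words in NOUN_CATEGORIES.items() for w in words
}
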