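"""Name -> metabolite-id maps for interface-set construction.

The interface sets are defined by compound *names* (acetate, the 20
universal amino acids, ...); the ids those names carry in a given reaction
database are configuration, not code, so synthetic databases may name them
freely.  Defaults match the ids used by :mod:`rumennet.synthetic`.
Override with a YAML file of the same two-level shape.
"""

from __future__ import annotations

from pathlib import Path

import yaml

AMINO_ACID_NAMES = [
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
]

DEFAULT_ID_MAP: dict[str, dict[str, str]] = {
    "vfa": {
        "acetate": "ACETATE",
        "propionate": "PROPIONATE",
        "butyrate": "BUTYRATE",
    },
    "amino_acids": {name: f"AA_{name.upper()}" for name in AMINO_ACID_NAMES},
}


def load_id_map(path: str | Path | None = None) -> dict[str, dict[str, str]]:
    """Return the interface id map, optionally overridden from YAML."""
    if path is None:
        return {k: dict(v) for k, v in DEFAULT_ID_MAP.items()}
    data = yaml.safe_load(Path(path).read_text())
    merged = {k: dict(v) for k, v in DEFAULT_ID_MAP.items()}
    for section, mapping in (data or {}).items():
        merged.setdefault(section, {}).update(mapping)
    return merged
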