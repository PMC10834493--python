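"""Bundled example data: the vildagliptin 50 mg tablet study.

Seven marketed products — the innovator (Galvus 50 mg, label ``Ref``)
and six generics (``V-1`` … ``V-6``) — sampled at 10, 15, 20, 30 and
45 min in 1000 mL of 0.01 N HCl (paddle, 50 rpm, 37 °C), reported as
per-time mean ± SD of n = 3 replicates.  The published table is
summary-level, so the bundled profiles are summary-only.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .profiles import Study, load_study

REFERENCE_LABEL = "Ref"


def vildagliptin_csv_path() -> Path:
    """Filesystem path of the bundled summary-layout CSV."""
    return Path(str(resources.files("dissolvekit.data") / "vildagliptin_50mg.csv"))


def default_method() -> dict:
    """The paddle-method metadata shipped with the bundled study."""
    text = (resources.files("dissolvekit.data") / "method_default.yaml").read_text()
    return yaml.safe_load(text)


def load_vildagliptin_study() -> Study:
    """The bundled seven-product study as a :class:`~dissolvekit.profiles.Study`."""
    return load_study(
        vildagliptin_csv_path(),
        reference=REFERENCE_LABEL,
        layout="summary",
        method=default_method(),
    )
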