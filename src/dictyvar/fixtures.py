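"""Packaged fixtures transcribing the study's printed tables.

``table1.tsv`` — per-sample SNP counts and mean mapped depths (47 samples,
including the ancestor, whose depth is not printed); ``table2.tsv`` — the
38 called SNPs with gene, samples, consequence and impact;
``clone_screen_regions.tsv`` — the region-pooled clone-screen cell counts.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from .tables import data_path

FIXTURE_FILES = ("table1.tsv", "table2.tsv", "clone_screen_regions.tsv")


def make_fixtures(out_dir) -> list:
    """Copy the packaged fixture TSVs into ``out_dir`` (idempotent)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_FILES:
        dest = out / name
        shutil.copyfile(data_path(name), dest)
        written.append(dest)
    return written
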