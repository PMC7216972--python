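"""Optional real-data access for the EBMT chronic myeloid leukemia cohort.

The ``ebmt1`` table ships with the R package **mstate** (de Wreede, Fiocco
& Putter); it records, for 1977 CML patients transplanted by the European
Society for Blood and Marrow Transplantation, the times to relapse and to
death, an EBMT risk-score group (Low/Medium/High) and age at transplant.
This module exports it through ``Rscript`` at call time — R with mstate
must be installed; nothing is bundled with this package.

The competing-risks view used here: cause 1 = relapse, cause 2 = death
before relapse (non-relapse mortality, NRM), 0 = censored.  Restricting to
adults (age ≥ 18) leaves 1835 patients with 421 relapses, 641 NRM events
and 773 censored observations.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .data import CompetingRisksData

__all__ = ["load_ebmt1"]

_R_EXPORT = """
suppressMessages(library(mstate))
data(ebmt1)
write.csv(ebmt1, file = "{out}", row.names = FALSE)
"""


def load_ebmt1(adults_only: bool = True) -> CompetingRisksData:
    """Load the EBMT CML cohort as competing-risks data via Rscript.

    Returns columns ``time`` (days), ``status`` (0/1/2 as above), ``age``
    (years), ``agedec`` (age centered at 40, per decade), ``score`` (risk
    group label) and dummy columns ``medium``/``high`` against the
    "Low risk" reference.

    Raises ``RuntimeError`` when Rscript or the mstate package is missing.
    """
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript not found; the EBMT demo needs R with mstate")
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "ebmt1.csv"
        proc = subprocess.run(
            ["Rscript", "-e", _R_EXPORT.format(out=out.as_posix())],
            capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise RuntimeError(
                f"exporting ebmt1 from R mstate failed: {proc.stderr.strip()}")
        raw = pd.read_csv(out)
    if adults_only:
        raw = raw[raw["age"] >= 18]
    relapse = raw["relstat"] == 1
    death_first = (raw["srvstat"] == 1) & ~relapse
    frame = pd.DataFrame({
        "time": raw["rel"].where(relapse, raw["srv"]).astype(float),
        "status": relapse.astype(int) + 2 * death_first.astype(int),
        "age": raw["age"].astype(float),
        "agedec": (raw["age"].astype(float) - 40.0) / 10.0,
        "score": raw["score"],
        "medium": (raw["score"] == "Medium risk").astype(float),
        "high": (raw["score"] == "High risk").astype(float),
    })
    return CompetingRisksData(frame.reset_index(drop=True))
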