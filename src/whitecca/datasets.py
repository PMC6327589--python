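"""Loaders for reference datasets used in examples and validation.

The nutrigenomic mouse study (40 animals; expression of 120 liver genes and
concentrations of 21 hepatic fatty acids) is the classic two-table CCA
benchmark.  It is distributed with the Bioconductor ``mixOmics`` R package;
the loader below extracts it through ``Rscript`` at run time, so an R
installation with mixOmics must be available on PATH.  No data are bundled
with this package.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

_R_SNIPPET = """
e <- new.env()
data(nutrimouse, package="mixOmics", envir=e)
write.csv(e$nutrimouse$gene, file.path("{out}", "gene.csv"))
write.csv(e$nutrimouse$lipid, file.path("{out}", "lipid.csv"))
"""


def load_nutrimouse() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the nutrimouse gene-expression (40x120) and lipid (40x21) tables.

    Returns ``(gene, lipid)`` data frames with matched rows (one per mouse).

    Raises
    ------
    RuntimeError
        If Rscript or the mixOmics package is unavailable.
    """
    with tempfile.TemporaryDirectory() as tmp:
        script = Path(tmp) / "export.R"
        script.write_text(_R_SNIPPET.format(out=tmp))
        try:
            proc = subprocess.run(
                ["Rscript", "--vanilla", str(script)],
                capture_output=True, text=True, timeout=120,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise RuntimeError(f"could not run Rscript: {exc}") from exc
        if proc.returncode != 0:
            raise RuntimeError(
                f"Rscript failed to export the nutrimouse data: {proc.stderr}"
            )
        gene = pd.read_csv(Path(tmp) / "gene.csv", index_col=0)
        lipid = pd.read_csv(Path(tmp) / "lipid.csv", index_col=0)
    if gene.shape != (40, 120) or lipid.shape != (40, 21):
        raise RuntimeError(
            f"unexpected nutrimouse shapes: {gene.shape}, {lipid.shape}"
        )
    if not np.all(gene.index == lipid.index):
        lipid = lipid.loc[gene.index]
    return gene, lipid
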