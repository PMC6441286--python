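#!/usr/bin/env python
"""Fetch and convert the example cancer-mutation data (needs network + R).

The contingency table (mutated genes x 12 cancer types, 3281 tumors,
derived from the Kandoth et al. pan-cancer mutation supplement) and the
gene -> annotation-group vector ship as ``.rda`` files inside the
MEUSassociation R package:

    https://github.com/mpiwowar/MEUSassociation.git

They are not vendored in this repository.  This script clones the package,
loads the R data objects with ``Rscript`` and writes them into the TSV
dialect used everywhere else:

    data/cancer_mutations.tsv              labelled count matrix
    data/cancer_mutations_gene_groups.tsv  two columns: gene, group

Run on a machine with network access; afterwards both the external
acceptance tests and scripts/acceptance.py pick the files up automatically.
"""

from __future__ import annotations

import subprocess
import sys
import tempfile
from pathlib import Path

REPO_URL = "https://github.com/mpiwowar/MEUSassociation.git"
ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "data"

R_CONVERT = r"""
args <- commandArgs(trailingOnly = TRUE)
pkg_dir <- args[1]
out_dir <- args[2]
for (rda in list.files(file.path(pkg_dir, "data"), pattern = "\\.rda$|\\.RData$",
                       full.names = TRUE)) {
  load(rda)
}
stopifnot(exists("cancer_mutations"), exists("cancer_mutations_gene_groups"))
m <- as.matrix(cancer_mutations)
write.table(m, file.path(out_dir, "cancer_mutations.tsv"),
            sep = "\t", quote = FALSE, col.names = NA)
g <- cancer_mutations_gene_groups
labels <- names(g)
if (is.null(labels)) {
  # unnamed vector: align with whichever matrix axis has matching length
  if (length(g) == nrow(m)) labels <- rownames(m)
  else if (length(g) == ncol(m)) labels <- colnames(m)
  else stop("gene-group vector matches neither matrix axis")
}
write.table(data.frame(gene = labels, group = as.character(g)),
            file.path(out_dir, "cancer_mutations_gene_groups.tsv"),
            sep = "\t", quote = FALSE, row.names = FALSE, col.names = FALSE)
cat("converted", length(labels), "gene labels,", nrow(m), "x", ncol(m), "matrix\n")
"""


def main() -> int:
    DATA_DIR.mkdir(exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        clone = Path(tmp) / "MEUSassociation"
        subprocess.run(["git", "clone", "--depth", "1", REPO_URL, str(clone)], check=True)
        script = Path(tmp) / "convert.R"
        script.write_text(R_CONVERT, encoding="utf-8")
        subprocess.run(
            ["Rscript", str(script), str(clone), str(DATA_DIR)], check=True
        )
    print(f"wrote TSV files under {DATA_DIR}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
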