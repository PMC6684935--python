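#!/usr/bin/env python
"""Bookkeeping and saturation checks against locally downloaded matrices.

Given a supermatrix alignment (FASTA or relaxed PHYLIP) and optionally a
tree with branch lengths, this prints the matrix dimensions, completeness
(both with and without counting 'X' as missing), and -- when a tree is
supplied -- the R^2 of the uncorrected-vs-patristic saturation regression.

Intended for checking deposited study matrices that are not bundled here
(they must be downloaded separately); it runs equally on any alignment.

Usage:
    python scripts/external_checks.py --alignment MatrixA.phy [--tree A.nwk]
"""

from __future__ import annotations

import argparse
import json

import phylomatrix as pm


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--alignment", required=True)
    parser.add_argument("--tree", default=None)
    args = parser.parse_args()

    with open(args.alignment) as fh:
        first = fh.readline()
    reader = pm.read_fasta if first.startswith(">") else pm.read_phylip
    matrix = reader(args.alignment)

    out = {
        "n_taxa": matrix.n_taxa,
        "n_columns": matrix.n_columns,
        "completeness_pct_x_missing": round(
            pm.completeness(matrix, count_x_as_missing=True), 2),
        "completeness_pct_x_present": round(
            pm.completeness(matrix, count_x_as_missing=False), 2),
    }
    if args.tree:
        import dendropy
        tree = dendropy.Tree.get(path=args.tree, schema="newick")
        fit = pm.saturation_fit(pm.p_distance_matrix(matrix),
                                pm.patristic_matrix(tree))
        out.update(r_squared=round(fit.r_squared, 3),
                   slope=round(fit.slope, 4), pairs_used=fit.pairs_used)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
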