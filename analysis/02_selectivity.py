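#!/usr/bin/env python
"""Selectivity of BC-7 and cisplatin for HeLa cells across cell lines.

Computes SI = IC50(comparator) / IC50(HeLa) for the normal comparators
(Vero, MRHF) and the other cancer lines (MeWo, HepG2), propagating the
right-censored BC-7 IC50s (>200 uM) as one-sided bounds.  Finding: BC-7 is
selective for HeLa over MeWo/HepG2 (SI > 3.05, bounded) and Vero (2.58) but
shows general toxicity relative to MRHF fibroblasts (SI 1.70 < 2); cisplatin
clears the SI < 2 toxicity threshold against every comparator.

Writes results/selectivity_matrix.csv.
"""

from pathlib import Path

from combsyn.selectivity import SelectivityIndex, flag_general_toxicity, selectivity_matrix
from combsyn.study import IC50_BY_LINE

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    matrix = selectivity_matrix(
        IC50_BY_LINE, target_line="HeLa",
        comparator_lines=["Vero", "MRHF", "MeWo", "HepG2"],
    )
    matrix.to_csv(RESULTS / "selectivity_matrix.csv")
    print(matrix.to_string())
    for drug in matrix.index:
        for line in matrix.columns:
            raw = matrix.loc[drug, line]
            si = SelectivityIndex(float(raw.lstrip(">")), raw.startswith(">"))
            if flag_general_toxicity(si):
                print(f"general toxicity flag: {drug} vs {line} (SI {raw} < 2)")
    print(f"wrote {RESULTS / 'selectivity_matrix.csv'}")


if __name__ == "__main__":
    main()
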