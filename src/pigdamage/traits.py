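"""The seven ear/tail damage trait definitions.

Raw phenotypes are ear and tail damage scored 0-3 (0 = no damage, 3 = severe
damage, biting and necrosis not distinguished). Five derived definitions are
built from them:

========  =====================================================  =======
trait     definition                                             scale
========  =====================================================  =======
ED03      ear damage on the original scale                       0-3
TD03      tail damage on the original scale                      0-3
ED01      binary ear damage, 1[ED03 > 0]                         0-1
TD01      binary tail damage, 1[TD03 > 0]                        0-1
AD01      any damage, max(ED01, TD01)                            0-1
NBP       number of body parts affected, ED01 + TD01             0-2
SD06      summed damage, ED03 + TD03                             0-6
========  =====================================================  =======
"""

from __future__ import annotations

import pandas as pd

RAW_TRAITS = ["ED03", "TD03"]
DERIVED_TRAITS = ["ED01", "TD01", "AD01", "NBP", "SD06"]
TRAITS = ["ED03", "ED01", "TD03", "TD01", "AD01", "NBP", "SD06"]

#: phenotype CSV column order
PHENOTYPE_COLUMNS = [
    "animal", "line", "sex", "litter", "pen", "hys_birth", "hys_scoring",
    "scorer", "age_days", "birth_date", "ED03", "TD03",
]


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Populate the five derived damage traits from raw ED03/TD03 scores.

    Derived columns are always recomputed from the raw scores (never trusted
    from the input), so the operation is idempotent. Raises ``ValueError``
    naming the first offending row if a raw score is missing or outside 0-3.
    """
    out = table.copy()
    for col in RAW_TRAITS:
        if col not in out.columns:
            raise ValueError(f"phenotype table is missing raw score {col!r}")
        s = pd.to_numeric(out[col], errors="coerce")
        bad = s.isna() | (s < 0) | (s > 3) | (s != s.round())
        if bad.any():
            row = out.index[bad][0]
            raise ValueError(
                f"invalid {col} score at row {row!r}: {out.loc[row, col]!r} "
                "(expected an integer 0-3)"
            )
        out[col] = s.astype(int)
    out["ED01"] = (out["ED03"] > 0).astype(int)
    out["TD01"] = (out["TD03"] > 0).astype(int)
    out["AD01"] = out[["ED01", "TD01"]].max(axis=1)
    out["NBP"] = out["ED01"] + out["TD01"]
    out["SD06"] = out["ED03"] + out["TD03"]
    return out
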