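"""Fill the campaign's missing values by month-slice seasonal interpolation.

Reads the CSVs written by 01_simulate.py, imputes each series separately
(all Junes interpolated across years, etc.), and writes *_imputed.csv next
to them.  Reports how many values were filled per series.
"""

import pathlib

from planksync import impute_seasonal, read_series, write_series

DATA = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    for variable in ("phytoplankton", "zooplankton", "temperature"):
        series = read_series(DATA / f"{variable}.csv", "synthetic", variable)
        filled = impute_seasonal(series)
        write_series(filled, DATA / f"{variable}_imputed.csv")
        print(f"{variable}: {int(series.missing.sum())} of {series.n} values imputed "
              f"-> {variable}_imputed.csv")


if __name__ == "__main__":
    main()
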