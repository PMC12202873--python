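"""Cross-validate links into background checks with pairwise Granger tests.

For each of the five other variables as source and each lag order 1..7,
compares the restricted AR model of background checks against the full
model adding the source's lags.  Writes results/granger.csv.
"""
from pathlib import Path

from causalpanel import granger_scan, read_panel_csv
from causalpanel.granger import scan_to_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clean = read_panel_csv(RESULTS / "clean.csv")
    sink = clean.names.index("background_checks")
    results = granger_scan(clean, sink, lags=range(1, 8))
    frame = scan_to_frame(results)
    frame.to_csv(RESULTS / "granger.csv", index=False)
    print(f"{len(results)} tests (5 sources x 7 lag orders), "
          f"{(frame.p_value < 0.05).sum()} significant at alpha=0.05")
    sig = frame[frame.p_value < 0.05]
    print(sig.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
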