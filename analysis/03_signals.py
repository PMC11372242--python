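"""Disproportionality screening: combination vs each monotherapy.

Computes per-PT reporting odds ratios with 95% CIs and BCPNN IC/IC025
(Haldane-Anscombe corrected tables, min 3 index reports), flags safety
signals (ROR > 1, IC > 0, IC025 > 0) and writes the SOC frequency table
and forest-plot extracts.
"""

from _common import RESULTS_DIR, SEED, ensure_bundle

from faerspv.pipeline import RunConfig, run_pipeline

if __name__ == "__main__":
    bundle = ensure_bundle()
    out = RESULTS_DIR / "signals"
    results = run_pipeline(
        RunConfig(str(bundle), str(out), seed=SEED), stages=("cohort", "screen")
    )
    for label, screened in results["signals"].items():
        flagged = [r for r in screened if r.is_signal]
        print(f"{label}: {len(screened)} terms screened, {len(flagged)} flagged")
        for r in screened[:5]:
            print(
                f"  {r.event_term:35s} ROR {r.ror:8.2f} "
                f"({r.ci_low:7.2f}-{r.ci_high:9.2f})  IC {r.ic:5.2f} "
                f"IC025 {r.ic025:5.2f}  signal={r.is_signal}"
            )
    print(f"tables written to {out}")
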