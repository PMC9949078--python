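"""Run-once fixture generation: edgeR TMM factors and R t.test oracle values.

Writes tests/data/tmm_edger_factors.json and tests/data/ttest_r_oracle.json.
Requires Rscript with edgeR and jsonlite on PATH.
"""
import json
import subprocess
import sys
import tempfile
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from helpers import nb_counts  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "tests" / "data"
DATA.mkdir(parents=True, exist_ok=True)

tmp = Path(tempfile.mkdtemp())
for seed in range(20):
    nb_counts(seed).to_csv(tmp / f"m{seed}.csv")

r_script = tmp / "oracle.R"
r_script.write_text(
    f"""
suppressMessages(library(edgeR))
out <- list()
for (seed in 0:19) {{
  x <- read.csv(file.path("{tmp}", sprintf("m%d.csv", seed)), row.names = 1)
  f <- calcNormFactors(as.matrix(x), method = "TMM")
  out[[sprintf("seed%d", seed)]] <- as.numeric(f)
}}
welch <- t.test(c(10,12,11,13), c(20,19,21,22), var.equal = FALSE)
x8 <- c(101.3, 98.7, 105.2, 99.9, 102.4, 97.1, 103.8, 100.6)
y9 <- c(104.9, 108.2, 103.1, 110.5, 106.7, 102.8, 109.3, 105.4, 107.6)
student <- t.test(x8, y9, var.equal = TRUE)
welch89 <- t.test(x8, y9, var.equal = FALSE)
fmt <- function(tt) list(t = unname(tt$statistic), df = unname(tt$parameter), p = tt$p.value)
res <- list(tmm = out,
            welch_4v4 = fmt(welch),
            student_8v9 = fmt(student),
            welch_8v9 = fmt(welch89))
cat(jsonlite::toJSON(res, digits = I(17), auto_unbox = TRUE))
"""
)
proc = subprocess.run(["Rscript", str(r_script)], capture_output=True, text=True, check=True)
res = json.loads(proc.stdout)
(DATA / "tmm_edger_factors.json").write_text(json.dumps(res["tmm"], indent=2))
(DATA / "ttest_r_oracle.json").write_text(
    json.dumps(
        {k: res[k] for k in ("welch_4v4", "student_8v9", "welch_8v9")}, indent=2
    )
)
print("wrote", DATA / "tmm_edger_factors.json")
print("wrote", DATA / "ttest_r_oracle.json")
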