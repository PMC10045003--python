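#!/usr/bin/env Rscript
# Optional extra: export the lung-cancer training/test cohorts from the
# compound.Cox R package (CRAN) so the full sensitivity grid can be run on
# the real data.  Requires network access to install compound.Cox; this
# script is NOT part of the test surface and nothing in the package
# depends on its output.
#
# Usage:
#   Rscript scripts/fetch_lung_data.R out_dir/
# then, with the prognostic index added from a signature file:
#   cgsurv grid --input out_dir/lung_test_pi.csv --cutoff-file \
#       out_dir/lung_train_pi.csv --nperm 10000 --seed 7 --out report/

args <- commandArgs(trailingOnly = TRUE)
out_dir <- if (length(args) >= 1) args[[1]] else "lung_data"
dir.create(out_dir, showWarnings = FALSE, recursive = TRUE)

if (!requireNamespace("compound.Cox", quietly = TRUE)) {
  install.packages("compound.Cox", repos = "https://cloud.r-project.org")
}
library(compound.Cox)
data(Lung)

train <- Lung[Lung$train == TRUE, ]
test <- Lung[Lung$train == FALSE, ]
write.csv(train, file.path(out_dir, "lung_train.csv"), row.names = FALSE)
write.csv(test, file.path(out_dir, "lung_test.csv"), row.names = FALSE)

# prognostic index under the shipped 16-gene signature
sig <- read.csv(file.path("src", "cgsurv", "fixtures", "emura_chen_16gene.csv"))
pi_of <- function(d) as.matrix(d[, sig$gene]) %*% sig$weight
train_out <- data.frame(time = train$t.vital, status = train$death,
                        pi = pi_of(train))
test_out <- data.frame(time = test$t.vital, status = test$death,
                       pi = pi_of(test))
write.csv(train_out, file.path(out_dir, "lung_train_pi.csv"), row.names = FALSE)
write.csv(test_out, file.path(out_dir, "lung_test_pi.csv"), row.names = FALSE)
cat("wrote", out_dir, "\n")
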