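# Independent oracle: Bioconductor limma's voom + lmFit + eBayes + contrasts.fit
# on the tiny frozen count fixture. Run from the repository root with:
#   Rscript tests/data/make_limma_oracle.R
# Regenerates limma_oracle_expected.tsv and limma_oracle_meta.tsv.
suppressMessages(library(limma))
counts <- as.matrix(read.delim("tests/data/limma_oracle_counts.tsv", row.names = 1))
stages <- read.delim("tests/data/limma_oracle_stages.tsv", row.names = 1)$stage
stages <- factor(stages, levels = c("control", "I", "II", "III", "IV"))

# baseline design: intercept + stage indicators
design <- model.matrix(~stages)
colnames(design) <- c("intercept", "I", "II", "III", "IV")
v <- voom(counts, design, span = 0.5)
fit <- eBayes(lmFit(v, design))
Fp <- fit$F.p.value
Fsub <- classifyTestsF(fit[, 2:5], fstat.only = TRUE)   # F over the four stage coefficients
Fsub_p <- pf(as.vector(Fsub), attr(Fsub, "df1"), attr(Fsub, "df2")[1], lower.tail = FALSE)

# cell-means design + stage-vs-control and between-stage contrasts
design2 <- model.matrix(~0 + stages)
colnames(design2) <- c("control", "I", "II", "III", "IV")
v2 <- voom(counts, design2, span = 0.5)
fit2 <- lmFit(v2, design2)
Csc <- makeContrasts(I = I - control, II = II - control,
                     III = III - control, IV = IV - control, levels = design2)
csc <- eBayes(contrasts.fit(fit2, Csc))
Cbs <- makeContrasts(I_vs_II = II - I, I_vs_III = III - I, II_vs_III = III - II,
                     I_vs_IV = IV - I, II_vs_IV = IV - II, III_vs_IV = IV - III,
                     levels = design2)
cbs <- eBayes(contrasts.fit(fit2, Cbs))

out <- data.frame(
  gene = rownames(counts),
  logcpm_s00 = v$E[, 1],
  weight_s00 = v$weights[, 1],
  weight_s19 = v$weights[, 20],
  sigma = fit$sigma,
  coef_I = fit$coefficients[, "I"],
  t_I = fit$t[, "I"],
  p_I = fit$p.value[, "I"],
  F = fit$F,
  F_p = Fp,
  F_stage = as.vector(Fsub),
  F_stage_p = Fsub_p,
  sc_lfc_I = csc$coefficients[, "I"],
  sc_p_I = csc$p.value[, "I"],
  bs_p_I_vs_II = cbs$p.value[, "I_vs_II"]
)
write.table(out, "tests/data/limma_oracle_expected.tsv",
            sep = "\t", quote = FALSE, row.names = FALSE)
meta <- data.frame(
  d0 = fit$df.prior, s02 = fit$s2.prior,
  d0_cm = csc$df.prior, s02_cm = csc$s2.prior
)
write.table(meta, "tests/data/limma_oracle_meta.tsv",
            sep = "\t", quote = FALSE, row.names = FALSE)
cat("d0 =", fit$df.prior, " s02 =", fit$s2.prior, "\n")
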