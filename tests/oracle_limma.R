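# Independent reference for the precision-weighted moderated-t pipeline:
# voom + lmFit + eBayes from Bioconductor limma, on a counts TSV whose
# first n_inact columns are the inactivated group.
# Usage: Rscript oracle_limma.R counts.tsv n_inact out.tsv
args <- commandArgs(trailingOnly = TRUE)
suppressPackageStartupMessages(library(limma))
counts <- as.matrix(read.delim(args[1], row.names = 1, check.names = FALSE))
n_inact <- as.integer(args[2])
n <- ncol(counts)
group <- c(rep(1, n_inact), rep(0, n - n_inact))
design <- cbind(intercept = 1, group = group)
v <- voom(counts, design, span = 0.5)
fit <- eBayes(lmFit(v, design))
out <- data.frame(gene = rownames(counts),
                  logFC = fit$coefficients[, "group"],
                  t = fit$t[, "group"],
                  p = fit$p.value[, "group"])
out$d0 <- fit$df.prior
out$s0sq <- fit$s2.prior
write.table(out, args[3], sep = "\t", quote = FALSE, row.names = FALSE)
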