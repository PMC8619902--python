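# Independent reference p-values for the five dispatched tests.
# Usage: Rscript r_reference.R <fixtures.json> <out.csv>
# Each fixture: {id, test, x, y|g|table}.  Spearman uses the asymptotic
# t approximation (exact=FALSE), chi-squared uses no continuity correction,
# matching the conventions of the engine under test.
suppressMessages(library(jsonlite))

args <- commandArgs(trailingOnly = TRUE)
fx <- fromJSON(args[1], simplifyVector = FALSE)
ids <- numeric(0)
ps <- numeric(0)
for (f in fx) {
  t <- f$test
  if (t == "pearson") {
    p <- cor.test(unlist(f$x), unlist(f$y), method = "pearson")$p.value
  } else if (t == "spearman") {
    p <- cor.test(unlist(f$x), unlist(f$y), method = "spearman", exact = FALSE)$p.value
  } else if (t == "chi_squared") {
    m <- do.call(rbind, lapply(f$table, unlist))
    p <- chisq.test(m, correct = FALSE)$p.value
  } else if (t == "anova") {
    p <- summary(aov(unlist(f$x) ~ factor(unlist(f$g))))[[1]][["Pr(>F)"]][1]
  } else if (t == "kruskal_wallis") {
    p <- kruskal.test(unlist(f$x), factor(unlist(f$g)))$p.value
  } else {
    stop(paste("unknown test:", t))
  }
  ids <- c(ids, f$id)
  ps <- c(ps, p)
}
out <- data.frame(id = ids, p = ps)
write.csv(format(out, digits = 17), args[2], row.names = FALSE)
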