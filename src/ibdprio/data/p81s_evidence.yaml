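# ACMG/AMP evidence satisfied by the index PAX6 missense variant (p.P81S):
# two moderate criteria and four supporting criteria.
codes:
  - PM1   # located in the paired domain, a missense hotspot without benign variation
  - PM2   # absent from gnomAD exomes
  - PP1   # co-segregates with diabetes in both sib-pairs and their mothers
  - PP2   # PAX6 is constrained against missense variation (gnomAD Z = 2.48)
  - PP3   # deleterious by SIFT / PolyPhen2 / PROVEAN, conserved across the PAX family
  - PP4   # three-generation dominant diabetes, one diagnosis at age 31
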