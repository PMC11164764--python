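# Published male per-stage mean ages (years) of the reference-study case
# groups for medial clavicular ossification staging.
# sd_age required: the per-stage SDs are not reproduced here; supply them from
# the original reference studies before this table can drive the
# stage-given-age model (the loader rejects rows without sd_age).
sex,stage,mean_age,sd_age,n
m,1,13.28,,
m,2a,17.40,,
m,2b,18.20,,
m,2c,18.60,,
m,3a,19.00,,
m,3b,21.10,,
m,3c,22.90,,
m,4,29.63,,
m,5,31.77,,
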