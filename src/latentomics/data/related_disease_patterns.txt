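# Disease-name patterns marking conditions obviously related to chronic
# kidney disease and myocardial infarction; features derived from matching
# diseases are removed from the latent-feature list.  "**" = any characters.
heart
**cardi**
athero**
arterio**
coronary
kidney
renal
nephro**
glomer**
diabe**
vascul**
capil**
hypertens**
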