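keyword,agent_class
glargine,basal_insulin
lantus,basal_insulin
detemir,basal_insulin
levemir,basal_insulin
degludec,basal_insulin
tresiba,basal_insulin
basalin,basal_insulin
nph,intermediate_insulin
isophane,intermediate_insulin
novolin n,intermediate_insulin
humulin n,intermediate_insulin
novolin 30r,intermediate_insulin
novolin 50r,intermediate_insulin
humulin 70/30,intermediate_insulin
mix,intermediate_insulin
premix,intermediate_insulin
gansulin 40r,intermediate_insulin
gansulin 30r,intermediate_insulin
novolin r,bolus_insulin
humulin r,bolus_insulin
gansulin r,bolus_insulin
aspart,bolus_insulin
novorapid,bolus_insulin
lispro,bolus_insulin
humalog,bolus_insulin
glulisine,bolus_insulin
apidra,bolus_insulin
regular insulin,bolus_insulin
insulin r,bolus_insulin
scilin r,bolus_insulin
metformin,non_insulin_agent
acarbose,non_insulin_agent
voglibose,non_insulin_agent
miglitol,non_insulin_agent
gliclazide,non_insulin_agent
glimepiride,non_insulin_agent
glipizide,non_insulin_agent
glibenclamide,non_insulin_agent
gliquidone,non_insulin_agent
sitagliptin,non_insulin_agent
vildagliptin,non_insulin_agent
saxagliptin,non_insulin_agent
linagliptin,non_insulin_agent
alogliptin,non_insulin_agent
liraglutide,non_insulin_agent
exenatide,non_insulin_agent
dulaglutide,non_insulin_agent
semaglutide,non_insulin_agent
dapagliflozin,non_insulin_agent
empagliflozin,non_insulin_agent
canagliflozin,non_insulin_agent
repaglinide,non_insulin_agent
nateglinide,non_insulin_agent
pioglitazone,non_insulin_agent
rosiglitazone,non_insulin_agent
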