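name,specification,details
vartable,basic,Table holding the indicators
var1,aids_cl_y == 1,Clinical AIDS at enrollment
var2,cd4_v_cmp < 200,Low baseline CD4
vartablesubset,"aids_cl_y in (0,1) and not missing(aids_cl_y) and not missing(cd4_v_cmp)",Rows with both indicators observed
eventdate,baseline_d,Enrollment date
eventperiod,year,One frame per calendar year
group,site,One bubble per site
var1label1,AIDS,
var1label0,no AIDS,
var2label1,<200,
var2label0,200+,
var1label,Proportion with clinical AIDS,
var2label,Proportion CD4<200 at enrollment in HIV care,
minnum,10,Minimum bubble denominator
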