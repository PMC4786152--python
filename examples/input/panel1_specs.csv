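name,specification,details
id,patient,Unique identifier in datasets
longtablename,lab_cd4,Table holding the longitudinal measure
longvar,cd4_v,Longitudinal variable
longvardate,cd4_d,Longitudinal variable date
longsubset,"cd4_v > 0 and not missing(cd4_v)",Keep positive non-missing values
eventtablename,follow,Table holding the event
event,death_y,Event indicator
enddate,l_alive_d,End of follow-up date
grouptablename,basic,Table holding the classifier
group,aids_y,Classifier
starttablename,art,Table holding the anchor date
startdate,art_sd,Anchor (ART start) date
starttype,first,first or last when multiple per id
longvartrans,sqrt,Axis transform
maxtime,730,Days of follow-up shown
long2eventwindow,360,Days a value may precede death and still mark it
longvarlim,"c(0,1500)",Y-axis limits on the original scale
longticks,"c(0,25,100,150,350,500,1000,2000,5000)",Tick values on the original scale
longlabel,CD4+ Count,
timelabel,Days from cART Start,
eventlabel,Cumulative Probability of Death,
grouplabels,0 = No AIDS|1 = AIDS,
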