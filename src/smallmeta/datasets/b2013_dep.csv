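study_id,available_data,measure,intervention,n_t,n_c,n_total,r
Abbott.2009.1,prepost-msds,DASS-D,Reslience program (online),26,27,53,-.10
Cheavens.2006.1,prepost-msds,CES-D,Hope therapy,16,16,32,.23
Fava.1998.1,prepost-msds,CID-DEP,Well-being therapy,10,10,20,.53
Fava.1998.1,prepost-msds,SQ-DEP,Well-being therapy,10,10,20,.04
Fava.2005.1,prepost-msds,CID-DEP,Well-being therapy,8,8,16,.28
Fava.2005.1,prepost-msds,SQ-DEP,Well-being therapy,8,8,16,.22
Gander.2013.1,prepost-msds,CES-D,Gratitude visit,61,63,124,-.10
Gander.2013.1,prepost-msds,CES-D,Three good things,87,63,150,-.01
Gander.2013.1,prepost-msds,CES-D,Signature strengths in a new way,73,63,136,-.06
Gander.2013.1,prepost-msds,CES-D,Three good things in the last two weeks,64,63,127,.00
Gander.2013.1,prepost-msds,CES-D,Gratitude visit & three good things,60,63,123,.10
Gander.2013.1,prepost-msds,CES-D,Three funny things,55,63,118,-.06
Gander.2013.1,prepost-msds,CES-D,Counting kindness,62,63,125,-.03
Gander.2013.1,prepost-msds,CES-D,Gift of time,55,63,118,-.10
Gander.2013.1,prepost-msds,CES-D,"One door closes, another opens",42,63,105,.04
Grant.2009.1,prepost-msds,DASS-D,Leadership development program,20,21,41,.24
Hurley.2012.1,prepost-msds,BDI-II,Savouring the moment,94,99,193,.20
Lichter.1980.2,prepost-msds,BDI,Positive feeling statements,25,23,48,.20
Mitchell.2009.1,prepost-msds,DASS-D,Signature strengths in a new way,17,23,40,-.08
Mongrain.2011.1,prepost-msds,CES-D,Self-compassion,237,237,474,.15
Mongrain.2012.1,prepost-msds,CES-D,Positive early memories,90,84,174,.06
Mongrain.2012.1,prepost-msds,CES-D,Three good things,106,84,190,.12
Mongrain.2012.1,prepost-msds,CES-D,Signature strengths in a new way,75,84,159,.14
Schueller.2012.1,prepost-msds,CES-D,Three good things & signature strengths,326,355,681,.16
Schueller.2012.1,prepost-msds,CES-D,Three good things & signature strengths & gratitude visit & savouring,364,355,719,.18
Schueller.2012.1,prepost-msds,CES-D,Three good things & signature strengths & gratitude visit & savouring & active-constructing respondng & life summary,319,355,674,.05
Seligman.2005.1,prepost-msds,CES-D,Gratitude visit,80,70,150,.16
Seligman.2005.1,prepost-msds,CES-D,Three good things,59,70,129,.10
Seligman.2005.1,prepost-msds,CES-D,You at your best,68,70,138,.10
Seligman.2005.1,prepost-msds,CES-D,Signature strengths in a new way,66,70,136,.07
Seligman.2005.1,prepost-msds,CES-D,Identifying signature strengths,68,70,138,.03
Seligman.2006.1,prepost-msds,BDI-II,Positive psychotherapy,14,20,34,.22
Seligman.2006.2,prepost-msds,ZSRS,Positive psychotherapy,11,9,20,.47
Seligman.2006.2,post-msds,HRSD,Positive psychotherapy,11,9,20,.59
Sergeant.2011.1,prepost-nomsnosds,CES-D,Gratitude,,,,
Shapira.2010.1,prepost-msds,CES-D,Self-compassion,63,70,133,.06
Shapira.2010.1,prepost-msds,CES-D,Optimism,55,70,125,.17
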