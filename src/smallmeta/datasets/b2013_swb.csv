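study_id,available_data,measure,intervention,n_t,n_c,n_total,r
Buchanan.2010.1,post-msds,SWLS,Acts of kindness,28,28,56,.34
Burton.2004.1,post-msds,PA-NS,Positive experiences,48,42,90,.54
Emmons.2003.1,post-msds,PA-NS,Gratitude,65,67,132,.10
Emmons.2003.3,post-anovaF,PA-NS,Gratitude,33,32,65,.27
Emmons.2003.3,post-anovaF,global life appraisals,Gratitude,33,32,65,.42
Emmons.2003.3,post-anovaF,expectations—upcoming week,Gratitude,33,32,65,.28
Emmons.2003.3,post-tpvalue,PANAS-P-observer,Gratitude,26,26,52,.26
Friesqijk.2006.1,prepost-msds,SPF-IL,Self-management,79,86,165,.13
Grant.2009.1,prepost-msds,WWBI,Leadership development,20,21,41,.16
Grant.2012.1,prepost-msds,PANAS-P,Solution coaching,117,108,225,.19
Green.2006.1,prepost-msds,SWLS,Solution coaching,23,25,48,.45
Green.2006.1,prepost-msds,PANAS-P,Solution coaching,25,25,50,.39
Hurley.2012.1,prepost-msds,PANAS-X-P,Savoring the moment,94,99,193,.07
King.2001.1,post-msds,D&E-NP,Best possible self,19,16,35,-.04
King.2001.1,post-msds,D&E-NP,Write about trauma + best possible self,22,16,38,.25
Kremers.2006.1,prepost-msds,SPFILS,Self-management,46,73,119,.13
Layous.2013.1,prepost-difmsds,AAS-P,Best possible self,80,37,117,.13
Lichter.1980.2,prepost-msds,HAP-AFFECT,Positive feeling statements,25,23,48,.19
Lyubomirsky.2006.2,post-msds,SWLS,Write about best experience,24,36,60,-.14
Lyubomirsky.2006.2,post-msds,PANAS-P,Write about best experience,24,36,60,-.04
Lyubomirsky.2006.2,post-msds,SWLS,Talk about best experience,25,36,61,-.32
Lyubomirsky.2006.2,post-msds,PANAS-P,Talk about best experience,25,36,61,-.03
Lyubomirsky.2006.2,post-msds,SWLS,Think about best experience,26,36,62,.12
Lyubomirsky.2006.2,post-msds,PANAS-P,Think about best experience,26,36,62,-.10
Lyubomirsky.2011.1,prepost-difmsds,UPL+PL+SWLS+SHS,Gratitude,107,101,208,.08
Lyubomirsky.2011.1,prepost-difmsds,UPL+PL+SWLS+SHS,Optimism,111,101,212,.03
Martinez-Marti.2010.1,prepost-msds,PA-NS,Gratitude,41,34,75,.15
Mitchell.2009.1,prepost-msds,PWI-A,Signature strengths,17,23,40,.09
Mitchell.2009.1,prepost-msds,SWLS,Signature strengths,17,23,40,-.06
Mitchell.2009.1,prepost-msds,PANAS-P,Signature strengths,17,23,40,.05
Page.2013.1,prepost-msds,SWLS + PANAS-P–PANAS-N,Wellness,23,14,37,.16
Page.2013.1,prepost-msds,AWB,Wellness,23,14,37,.57
Peters.2010.1,prepost-msds,PANAS-Short-P,Positive future thinking,44,38,82,.49
Seligman.2006.1,prepost-msds,SWLS,Positive psychotherapy,14,20,34,-.01
Seligman.2006.2,prepost-msds,SWLS,Positive psychotherapy,11,9,20,.23
Shapira.2010.1,prepost-msds,SHI,Self-compassion,63,70,133,.01
Shapira.2010.1,prepost-msds,SHI,Optimism,55,70,125,.11
Sheldon.2006.1,prepost-msds,PANAS-P,Gratitude,21,23,44,-.08
Sheldon.2006.1,prepost-msds,PANAS-P,Best possible self,23,23,46,.30
Spence.2007.1,prepost-msds,SWLS,Professional coaching,20,17,37,.38
Spence.2007.1,prepost-msds,B-PA,Professional coaching,20,17,37,.16
Spence.2007.1,prepost-msds,SWLS,Peer coaching,20,17,37,.38
Spence.2007.1,prepost-msds,B-PA,Peer coaching,20,17,37,.25
Wing.2006.1,prepost-msds,SWLS,Positive experiences w/cue,58,55,113,-.11
Wing.2006.1,prepost-msds,SWLS,Positive experiences,62,55,117,-.05
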