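patient,age,sex,disease_duration_years,dci,ygtss_total,ygtss_tics,rush,comorbidities,medication
1,45,1,38,86,69,39,12,Depressive episode,"Pimozide, biperiden"
2,21,1,3,83,16,16,8,,
3,25,2,21,86,33,13,14,,
4,47,1,32,66,15,15,13,,
5,33,1,26,64,35,25,10,,
6,25,2,21,54,6,6,5,,
7,48,2,43,51,31,11,8,"Depression, burnout","Escitalopram, candesartan"
8,28,2,23,55,31,21,16,,
9,47,1,37,100,46,26,16,Depression,N/A
10,29,2,26,66,55,25,18,"Borderline personality disorder, anxiety disorder, depressive episode","Alprazolam (if needed, every 2-3 weeks)"
11,22,1,17,62,34,24,15,,Aripiprazole
12,20,1,11,90,39,29,19,,N/A
13,25,1,19,51,40,20,6,Depression,Pimozide
14,23,1,17,71,40,30,9,"Depression, OCD, social phobia",Aripiprazole
15,54,1,48,65,51,21,15,Depression,"Pantoprazol, paroxetine, simvastatin, korodin (if needed), mirtazapine (if needed), mometasonfuroat, sumatriptan"
16,50,1,40,38,0,0,3,,Aripiprazole
17,40,1,34,85,26,16,14,OCD,Citalopram
18,21,2,14,93,37,17,15,,
19,37,1,32,100,57,37,14,"ADHD, depressive episode",N/A
20,35,1,29,53,41,21,16,ADHD,Methylphenidate
21,30,1,24,48,18,18,,,
22,35,1,26,49,27,47,,,
23,35,1,25,45,20,20,,,
24,33,1,23,88,18,38,,,
25,42,1,17,76,25,45,,,
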